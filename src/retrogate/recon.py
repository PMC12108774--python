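"""K-space binning reconstruction.

Sorts timestamped k-space lines into cardiac-phase bins, applies zero-
and first-order phase correction against a reference measurement,
complex-averages each bin, and Fourier-reconstructs per-phase echo
images.  The ungated reference reconstruction (all measurements averaged
into one bin) is the gold standard the binned images are validated
against.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np

from .fourier import kspace_to_image
from .physio import DISCARD, DiscardReason, PhaseAssignment

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import ProtocolSpec

logger = logging.getLogger(__name__)

__all__ = [
    "ReconError",
    "KSpaceLineSet",
    "BinnedKSpace",
    "EchoImageSeries",
    "REFERENCE",
    "phase_correct",
    "bin_and_average",
    "reconstruct",
    "reconstruct_reference",
]

#: Phase label of the ungated (conventional) reconstruction.
REFERENCE = "REFERENCE"


class ReconError(RuntimeError):
    """Raised when reconstruction preconditions are violated."""


@dataclass(frozen=True)
class KSpaceLineSet:
    """Complex readout lines tagged with acquisition metadata.

    One "line" is a single excitation: all echoes of one phase-encode row
    share the excitation timestamp, so ``data`` has shape
    ``[n_lines, n_echoes, n_readout]``.  Every ``(measurement, pe)`` pair
    is unique.
    """

    data: np.ndarray  # complex [n_lines, n_echoes, n_readout]
    pe_index: np.ndarray  # int [n_lines]
    meas_index: np.ndarray  # int [n_lines]
    timestamps_ms: np.ndarray  # float [n_lines]
    protocol: "ProtocolSpec"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("data must be [n_lines, n_echoes, n_readout]")
        pe = np.asarray(self.pe_index, dtype=np.int64)
        meas = np.asarray(self.meas_index, dtype=np.int64)
        ts = np.asarray(self.timestamps_ms, dtype=float)
        if not (pe.size == meas.size == ts.size == data.shape[0]):
            raise ValueError("per-line metadata must align with data")
        key = meas * (pe.max() + 1 if pe.size else 1) + pe
        if np.unique(key).size != key.size:
            raise ValueError("(measurement, pe) pairs must be unique")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "pe_index", pe)
        object.__setattr__(self, "meas_index", meas)
        object.__setattr__(self, "timestamps_ms", ts)

    @property
    def n_lines(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_echoes(self) -> int:
        return int(self.data.shape[1])

    @property
    def n_readout(self) -> int:
        return int(self.data.shape[2])


@dataclass(frozen=True)
class BinnedKSpace:
    """Per-cardiac-phase complex k-space averages with occupancy counts."""

    data: np.ndarray  # complex [n_phases, n_echoes, n_pe, n_readout]
    counts: np.ndarray  # int [n_phases, n_echoes, n_pe]
    discarded: np.ndarray  # int [n_echoes, n_pe]
    n_phases: int
    protocol: "ProtocolSpec"

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.all(np.isfinite(self.data.real)) or not np.all(np.isfinite(self.data.imag)):
            raise ValueError("binned k-space must be finite")

    def fill_fraction(self, phase: int) -> float:
        """Fraction of (echo, pe) bins of this phase holding >= 1 line."""
        return float((self.counts[phase] > 0).mean())


@dataclass(frozen=True)
class EchoImageSeries:
    """Complex images across echo times for one cardiac phase."""

    images: np.ndarray  # complex [n_echoes, ny, nx]
    te: np.ndarray  # ms, ascending
    phase_label: int | str  # phase index or REFERENCE
    fill_fraction: float

    def __post_init__(self) -> None:
        te = np.asarray(self.te, dtype=float)
        object.__setattr__(self, "te", te)
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly ascending")
        if not 0.0 <= self.fill_fraction <= 1.0:
            raise ValueError("fill_fraction must lie in [0, 1]")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.images)


def phase_correct(
    lines: KSpaceLineSet,
    reference_measurement: int,
    chunk_size: int = 4096,
) -> KSpaceLineSet:
    """Zero- and first-order phase correction against a reference measurement.

    For each (echo, pe) the phase difference between a line and the
    reference measurement's matching line is unwrapped along the readout
    and fitted with a magnitude-weighted straight line in the sample index
    ``k`` (centered); the line is multiplied by ``exp(-i(phi0 + phi1*k))``.
    Reference lines are returned unchanged.  This stabilizes complex
    averaging against per-shot global phase drifts and small readout
    shifts.
    """
    ref_sel = lines.meas_index == reference_measurement
    if not np.any(ref_sel):
        raise ReconError(f"reference measurement {reference_measurement} not present")
    pe_all = np.unique(lines.pe_index)
    ref_pe = lines.pe_index[ref_sel]
    if np.setdiff1d(pe_all, ref_pe).size:
        raise ReconError("reference measurement is missing phase-encode lines")

    n_pe_max = int(lines.pe_index.max()) + 1
    ref_lookup = np.zeros((n_pe_max, lines.n_echoes, lines.n_readout), complex)
    ref_lookup[ref_pe] = lines.data[ref_sel]

    k = np.arange(lines.n_readout) - lines.n_readout // 2
    out = lines.data.copy()
    other = np.flatnonzero(~ref_sel)
    for lo in range(0, other.size, chunk_size):
        idx = other[lo : lo + chunk_size]
        d = lines.data[idx]  # [l, E, X]
        ref = ref_lookup[lines.pe_index[idx]]
        phase = np.unwrap(np.angle(d * np.conj(ref)), axis=-1)
        w = np.abs(d) * np.abs(ref)
        sw = w.sum(-1)
        sk = (w * k).sum(-1)
        skk = (w * k * k).sum(-1)
        sp = (w * phase).sum(-1)
        skp = (w * k * phase).sum(-1)
        denom = sw * skk - sk * sk
        safe = (denom > 0) & (sw > 0)
        denom = np.where(safe, denom, 1.0)
        phi1 = np.where(safe, (sw * skp - sk * sp) / denom, 0.0)
        phi0 = np.where(safe & (sw > 0), (sp - phi1 * sk) / np.where(sw > 0, sw, 1.0), 0.0)
        out[idx] = d * np.exp(-1j * (phi0[..., None] + phi1[..., None] * k))
    return replace(lines, data=out)


def bin_and_average(lines: KSpaceLineSet, assignment: PhaseAssignment) -> BinnedKSpace:
    """Complex-average k-space lines into cardiac-phase bins.

    Averaging is performed in the k-space domain: for each
    (phase, echo, pe) the accumulator holds the complex mean of all lines
    assigned to that phase; discarded lines are excluded but counted.
    Empty bins are legal here (zero-filled) and surface later through
    ``fill_fraction``.
    """
    if assignment.n_lines != lines.n_lines:
        raise ValueError("assignment does not cover the line set")
    n_phases = assignment.n_phases
    n_pe = int(lines.pe_index.max()) + 1
    acc = np.zeros((n_phases, n_pe, lines.n_echoes, lines.n_readout), complex)
    cnt = np.zeros((n_phases, n_pe), dtype=np.int64)

    kept = assignment.labels >= 0
    np.add.at(acc, (assignment.labels[kept], lines.pe_index[kept]), lines.data[kept])
    np.add.at(cnt, (assignment.labels[kept], lines.pe_index[kept]), 1)

    disc = np.zeros(n_pe, dtype=np.int64)
    np.add.at(disc, lines.pe_index[~kept], 1)

    mean = np.where(cnt[:, :, None, None] > 0, acc / np.maximum(cnt[:, :, None, None], 1), 0.0)
    data = mean.transpose(0, 2, 1, 3)  # [P, E, pe, X]
    counts = np.broadcast_to(cnt[:, None, :], (n_phases, lines.n_echoes, n_pe)).copy()
    discarded = np.broadcast_to(disc[None, :], (lines.n_echoes, n_pe)).copy()
    return BinnedKSpace(
        data=data, counts=counts, discarded=discarded, n_phases=n_phases, protocol=lines.protocol
    )


def reconstruct(
    binned: BinnedKSpace,
    phase: int,
    min_fill: float = 0.95,
    allow_partial: bool = False,
) -> EchoImageSeries:
    """Inverse-Fourier reconstruct one cardiac phase from binned k-space.

    Empty (echo, pe) bins are zero-filled with a warning; if the fill
    fraction drops below ``min_fill`` the reconstruction refuses unless
    ``allow_partial`` is set.
    """
    fill = binned.fill_fraction(phase)
    if fill < min_fill and not allow_partial:
        raise ReconError(
            f"phase {phase}: fill fraction {fill:.3f} below the minimum {min_fill:.2f}; "
            "pass allow_partial to reconstruct anyway"
        )
    if fill < 1.0:
        warnings.warn(
            f"phase {phase}: {(binned.counts[phase] == 0).sum()} empty k-space bins zero-filled "
            f"(fill fraction {fill:.3f})",
            RuntimeWarning,
            stacklevel=2,
        )
    images = kspace_to_image(binned.data[phase])
    return EchoImageSeries(
        images=images,
        te=binned.protocol.echo_times,
        phase_label=phase,
        fill_fraction=fill,
    )


def reconstruct_reference(lines: KSpaceLineSet, **kwargs) -> EchoImageSeries:
    """Conventional (ungated) MGE reconstruction: average all measurements.

    Equivalent to binning with a single all-inclusive phase and no
    discards, then reconstructing.
    """
    assignment = PhaseAssignment(
        labels=np.zeros(lines.n_lines, dtype=np.int64),
        reasons=np.full(lines.n_lines, int(DiscardReason.NONE), dtype=np.int64),
        n_phases=1,
    )
    binned = bin_and_average(lines, assignment)
    series = reconstruct(binned, 0, **kwargs)
    return replace(series, phase_label=REFERENCE)
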