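"""File formats.

* Simulated acquisitions travel in an HDF5 container:
  ``/kspace`` complex ``[n_lines, n_readout, n_echoes]``,
  ``/timestamps_ms``, ``/pe_index``, ``/meas_index``,
  ``/ttl/start_ms``, ``/ttl/end_ms``, ``/triggers_ms`` (optional),
  ``/ground_truth/s0`` and ``/ground_truth/t2star`` (optional),
  with the protocol stored as root attributes.
* Physio signals are two-column CSVs (``time_ms,value``), explicit
  triggers a single ``trigger_ms`` column, TTL events ``start_ms,end_ms``;
  every file starts with a ``# units: ms`` header line.
* Images and maps are written as NIfTI via nibabel: per-phase echo images
  as one 4-D file (x, y, echo, phase) with a JSON sidecar (echo times,
  counts, fill fractions, protocol), parameter maps as 3-D stacks.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .fitting import T2StarMap
from .phantom import ProtocolSpec, SimOutput
from .physio import TriggerTrain, TTLRecord
from .recon import EchoImageSeries, KSpaceLineSet

__all__ = [
    "write_sim_output",
    "read_kspace",
    "write_physio_csv",
    "read_physio_csv",
    "write_trigger_csv",
    "read_trigger_csv",
    "write_ttl_csv",
    "read_ttl_csv",
    "write_echo_images",
    "write_maps",
]

_UNITS_HEADER = "# units: ms\n"

_PROTOCOL_ATTRS = ("tr", "te1", "delta_te", "n_echoes", "n_measurements", "n_phases")


def write_sim_output(path: str | Path, sim: SimOutput) -> None:
    """Write a simulated acquisition to the HDF5 container."""
    lines = sim.kspace
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=lines.data.transpose(0, 2, 1))  # [L, X, E]
        f.create_dataset("timestamps_ms", data=lines.timestamps_ms)
        f.create_dataset("pe_index", data=lines.pe_index)
        f.create_dataset("meas_index", data=lines.meas_index)
        ttl = f.create_group("ttl")
        ttl.create_dataset("start_ms", data=sim.ttl.measurement_start_times)
        ttl.create_dataset("end_ms", data=sim.ttl.measurement_end_times)
        f.create_dataset("triggers_ms", data=sim.triggers.trigger_times)
        gt = f.create_group("ground_truth")
        for key, value in sim.ground_truth.items():
            gt.create_dataset(key, data=value)
        for name in _PROTOCOL_ATTRS:
            f.attrs[name] = getattr(lines.protocol, name)
        f.attrs["matrix"] = list(lines.protocol.matrix)
        f.attrs["noise_sd"] = sim.noise_sd
        f.attrs["seed"] = -1 if sim.seed is None else sim.seed


def read_kspace(path: str | Path) -> tuple[KSpaceLineSet, TTLRecord, TriggerTrain | None]:
    """Read a k-space container back into in-memory objects."""
    with h5py.File(path, "r") as f:
        protocol = ProtocolSpec(
            matrix=tuple(int(v) for v in f.attrs["matrix"]),
            **{name: f.attrs[name].item() for name in _PROTOCOL_ATTRS},
        )
        lines = KSpaceLineSet(
            data=f["kspace"][()].transpose(0, 2, 1),
            pe_index=f["pe_index"][()],
            meas_index=f["meas_index"][()],
            timestamps_ms=f["timestamps_ms"][()],
            protocol=protocol,
        )
        ttl = TTLRecord(f["ttl/start_ms"][()], f["ttl/end_ms"][()])
        triggers = None
        if "triggers_ms" in f:
            triggers = TriggerTrain(f["triggers_ms"][()], source="simulated")
    return lines, ttl, triggers


def write_physio_csv(path: str | Path, time_ms: np.ndarray, value: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write(_UNITS_HEADER)
        pd.DataFrame({"time_ms": time_ms, "value": value}).to_csv(fh, index=False)


def read_physio_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, comment="#")
    return df["time_ms"].to_numpy(float), df["value"].to_numpy(float)


def write_trigger_csv(path: str | Path, trigger_ms: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write(_UNITS_HEADER)
        pd.DataFrame({"trigger_ms": trigger_ms}).to_csv(fh, index=False)


def read_trigger_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, comment="#")["trigger_ms"].to_numpy(float)


def write_ttl_csv(path: str | Path, ttl: TTLRecord) -> None:
    with open(path, "w") as fh:
        fh.write(_UNITS_HEADER)
        pd.DataFrame(
            {"start_ms": ttl.measurement_start_times, "end_ms": ttl.measurement_end_times}
        ).to_csv(fh, index=False)


def read_ttl_csv(path: str | Path) -> TTLRecord:
    df = pd.read_csv(path, comment="#")
    return TTLRecord(df["start_ms"].to_numpy(float), df["end_ms"].to_numpy(float))


def _affine(fov: tuple[float, float], matrix: tuple[int, int]) -> np.ndarray:
    dy = fov[0] / matrix[0]
    dx = fov[1] / matrix[1]
    return np.diag([dx, dy, 1.0, 1.0])


def write_echo_images(
    path: str | Path,
    series_list: Sequence[EchoImageSeries],
    protocol: ProtocolSpec,
    counts: np.ndarray | None = None,
    fov: tuple[float, float] = (30.0, 30.0),
) -> None:
    """Write per-phase echo magnitude images as one 4-D NIfTI (x, y, echo, phase)
    plus a JSON sidecar with echo times, fill fractions, and line counts."""
    path = Path(path)
    stack = np.stack([s.magnitude for s in series_list], axis=-1)  # [E, ny, nx, P]
    vol = stack.transpose(2, 1, 0, 3)  # x, y, echo, phase
    nib.save(nib.Nifti1Image(vol, _affine(fov, protocol.matrix)), path)
    sidecar = {
        "te_ms": [float(t) for t in protocol.echo_times],
        "phase_labels": [s.phase_label for s in series_list],
        "fill_fractions": [s.fill_fraction for s in series_list],
        "protocol": {name: getattr(protocol, name) for name in _PROTOCOL_ATTRS},
        "counts_per_phase": None if counts is None else counts.tolist(),
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def write_maps(
    path_prefix: str | Path,
    maps: Sequence[T2StarMap],
    fov: tuple[float, float] = (30.0, 30.0),
) -> None:
    """Write per-phase T2*/S0/gof maps as 3-D NIfTI stacks (x, y, phase)."""
    prefix = Path(path_prefix)
    matrix = maps[0].t2star.shape
    aff = _affine(fov, matrix)
    for name in ("t2star", "s0", "gof"):
        vol = np.stack([getattr(m, name) for m in maps], axis=-1).transpose(1, 0, 2)
        nib.save(nib.Nifti1Image(vol, aff), prefix.parent / f"{prefix.name}_{name}.nii")
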