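"""Pixelwise mono-exponential T2* estimation.

The signal model is S(TE) = S0 * exp(-TE / T2*), fitted to magnitude
images per pixel and per cardiac phase.  Fitting is initialized from the
log-linear solution and refined by bounded nonlinear least squares
(T2* in [0.1, 100] ms by default, S0 > 0).  Goodness of fit is the
coefficient of determination on the magnitude scale.

Magnitude-domain fitting carries the well-known Rician noise-floor bias
at low SNR (fitted T2* biased upward as the late echoes flatten onto the
noise floor); the bias is surfaced through gof/masking rather than
modeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .recon import EchoImageSeries

__all__ = [
    "FitError",
    "PixelFit",
    "T2StarMap",
    "RoiSummary",
    "fit_pixel",
    "fit_map",
    "auto_mask",
    "phase_profile",
]

DEFAULT_BOUNDS = (0.1, 100.0)  # ms; brackets phantom (4-20) and in vivo (~8-12) regimes


class FitError(RuntimeError):
    """Raised on invalid fitting inputs (e.g. an empty mask)."""


class PixelFit(NamedTuple):
    s0: float
    t2star: float
    gof: float
    ok: bool


@dataclass(frozen=True)
class T2StarMap:
    """Per-phase parameter images from pixelwise fitting.

    Pixels outside ``mask`` (never fitted, flagged as non-convergent, at a
    bound, or without signal) hold NaN.
    """

    t2star: np.ndarray  # ms
    s0: np.ndarray
    gof: np.ndarray
    mask: np.ndarray  # bool: successfully fitted pixels
    phase_label: int | str = 0

    def __post_init__(self) -> None:
        inside = self.t2star[self.mask]
        if inside.size and (np.any(~np.isfinite(inside)) or np.any(inside <= 0)):
            raise ValueError("masked T2* values must be finite and positive")


@dataclass(frozen=True)
class RoiSummary:
    """Mean/SD/pixel-count of T2* over one ROI for one cardiac phase."""

    phase: int | str
    mean_ms: float
    sd_ms: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("an ROI summary needs at least one pixel")
        if self.sd_ms < 0:
            raise ValueError("sd must be non-negative")


def _model(params: np.ndarray, te: np.ndarray) -> np.ndarray:
    s0, t2 = params
    return s0 * np.exp(-te / t2)


def _residuals(params: np.ndarray, te: np.ndarray, y: np.ndarray) -> np.ndarray:
    return _model(params, te) - y


def _jacobian(params: np.ndarray, te: np.ndarray, y: np.ndarray) -> np.ndarray:
    s0, t2 = params
    e = np.exp(-te / t2)
    return np.column_stack([e, s0 * e * te / t2**2])


def fit_pixel(
    te: Sequence[float],
    magnitudes: Sequence[float],
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> PixelFit:
    """Fit S(TE) = S0 * exp(-TE / T2*) to one pixel's echo magnitudes.

    Parameters
    ----------
    te:
        Ascending echo times in ms (>= 3 echoes).
    magnitudes:
        Non-negative signal magnitudes, one per echo.
    bounds:
        (lower, upper) admissible T2* in ms.

    Returns
    -------
    PixelFit
        ``(s0, t2star, gof, ok)``.  ``ok`` is False for no-signal pixels,
        non-convergent fits, and fits pinned at the T2* bounds (e.g. a
        non-decaying pixel driven to the upper bound); such pixels are
        excluded from maps and ROI summaries.
    """
    te = np.asarray(te, dtype=float)
    y = np.asarray(magnitudes, dtype=float)
    if te.size < 3:
        raise FitError("need at least 3 echoes to fit a decay")
    if np.any(np.diff(te) <= 0):
        raise FitError("echo times must be strictly ascending")
    if np.any(y < 0):
        raise FitError("magnitudes must be non-negative")
    lo, hi = bounds
    if not 0 < lo < hi:
        raise FitError("bounds must satisfy 0 < lower < upper")

    if not np.any(y > 0):
        return PixelFit(np.nan, np.nan, np.nan, False)

    # log-linear initialization on the positive samples
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(te[pos], np.log(y[pos]), 1, w=y[pos])
        t2_init = -1.0 / slope if slope < 0 else hi
        s0_init = float(np.exp(intercept))
    else:
        t2_init, s0_init = float(np.sqrt(lo * hi)), float(y.max())
    t2_init = float(np.clip(t2_init, lo, hi))
    s0_init = max(s0_init, float(np.finfo(float).tiny))

    res = least_squares(
        _residuals,
        x0=[s0_init, t2_init],
        jac=_jacobian,
        bounds=([0.0, lo], [np.inf, hi]),
        args=(te, y),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    s0_fit, t2_fit = res.x
    ss_res = float(np.sum((_model(res.x, te) - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    gof = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    rel_margin = 1e-6 * (hi - lo)
    at_bound = t2_fit >= hi - rel_margin or t2_fit <= lo + rel_margin
    ok = bool(res.success and not at_bound and s0_fit > 0 and ss_tot > 0)
    return PixelFit(float(s0_fit), float(t2_fit), float(gof), ok)


def auto_mask(series: EchoImageSeries, threshold_factor: float = 5.0) -> np.ndarray:
    """Signal mask: first-echo magnitude above ``threshold_factor`` x background SD.

    The background noise level is estimated from the border frame of the
    first-echo magnitude image (outer sixteenth on each side), which is
    signal-free for centered phantoms.  The threshold is floored at 0.1%
    of the image maximum so that (near-)noiseless images still yield a
    clean signal mask.
    """
    mag0 = series.magnitude[0]
    ny, nx = mag0.shape
    by, bx = max(2, ny // 16), max(2, nx // 16)
    border = np.ones_like(mag0, dtype=bool)
    border[by : ny - by, bx : nx - bx] = False
    sd = float(mag0[border].std())
    threshold = max(threshold_factor * sd, 1e-3 * float(mag0.max()))
    return mag0 > threshold


def fit_map(
    series: EchoImageSeries,
    mask: np.ndarray | None = None,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    min_gof: float | None = None,
) -> T2StarMap:
    """Pixelwise T2* fit of an echo-image series within a mask.

    Parameters
    ----------
    series:
        Reconstructed echo images of one cardiac phase (or the reference).
    mask:
        Boolean image selecting pixels to fit; defaults to :func:`auto_mask`.
    bounds:
        Admissible T2* range in ms.
    min_gof:
        If given, pixels with gof below this are dropped from the map mask.
    """
    mag = series.magnitude
    if mask is None:
        mask = auto_mask(series)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != mag.shape[1:]:
        raise FitError("mask geometry does not match the images")
    if not mask.any():
        raise FitError("empty fitting mask")

    ny, nx = mask.shape
    t2 = np.full((ny, nx), np.nan)
    s0 = np.full((ny, nx), np.nan)
    gof = np.full((ny, nx), np.nan)
    ok = np.zeros((ny, nx), dtype=bool)
    te = series.te
    ys = mag[:, mask].T  # [n_masked, n_echoes]
    rows, cols = np.nonzero(mask)
    for (r, c, y) in zip(rows, cols, ys):
        fit = fit_pixel(te, y, bounds=bounds)
        t2[r, c], s0[r, c], gof[r, c] = fit.t2star, fit.s0, fit.gof
        ok[r, c] = fit.ok
    if min_gof is not None:
        ok &= np.nan_to_num(gof, nan=-np.inf) >= min_gof
    t2[~ok] = np.nan
    s0[~ok] = np.nan
    return T2StarMap(t2star=t2, s0=s0, gof=gof, mask=ok, phase_label=series.phase_label)


def phase_profile(
    maps: Sequence[T2StarMap],
    roi: np.ndarray,
) -> tuple[pd.DataFrame, float]:
    """ROI T2* summary per cardiac phase plus the cycle average.

    Pixels with non-positive gof are excluded from the summaries.  If the
    ROI extends outside a map's fitted mask, a warning is emitted and the
    intersection is used.

    Returns
    -------
    (profile, cycle_mean)
        ``profile`` has columns ``phase, mean_ms, sd_ms, n_pixels``;
        ``cycle_mean`` is the unweighted mean of the per-phase means.
    """
    roi = np.asarray(roi, dtype=bool)
    rows = []
    for m in maps:
        if roi.shape != m.mask.shape:
            raise ValueError("all maps and the ROI must share geometry")
        usable = m.mask & (np.nan_to_num(m.gof, nan=-np.inf) > 0)
        sel = roi & usable
        if sel.sum() < roi.sum():
            warnings.warn(
                f"phase {m.phase_label}: ROI extends outside the fitted mask; "
                f"using the intersection ({int(sel.sum())}/{int(roi.sum())} pixels)",
                RuntimeWarning,
                stacklevel=2,
            )
        if not sel.any():
            raise FitError(f"phase {m.phase_label}: ROI contains no fitted pixels")
        vals = m.t2star[sel]
        rows.append(
            RoiSummary(
                phase=m.phase_label,
                mean_ms=float(vals.mean()),
                sd_ms=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                n_pixels=int(vals.size),
            )
        )
    profile = pd.DataFrame(
        {
            "phase": [r.phase for r in rows],
            "mean_ms": [r.mean_ms for r in rows],
            "sd_ms": [r.sd_ms for r in rows],
            "n_pixels": [r.n_pixels for r in rows],
        }
    )
    return profile, float(profile["mean_ms"].mean())
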