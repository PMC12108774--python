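"""Validation and cohort statistics.

Implements the method-comparison toolbox used to validate retrospective
binning against the conventional reference reconstruction, plus the
nonparametric tests applied to per-subject, per-phase T2* tables:

* :func:`nema_snr` — NEMA single-image SNR (Rayleigh-corrected magnitude
  background).
* :func:`method_agreement` — OLS regression, Pearson R^2, ICC (two-way,
  absolute agreement, single measures), and Bland-Altman bias with 95%
  limits of agreement.
* :func:`phase_stats` — Friedman test across cardiac phases, Holm-adjusted
  pairwise Wilcoxon signed-rank tests, Mann-Whitney U group comparisons on
  cycle-averaged T2*, and Spearman correlations against covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "PhaseStatsReport",
    "nema_snr",
    "method_agreement",
    "phase_stats",
    "spearman_strength",
    "significance_stars",
    "RAYLEIGH_CORRECTION",
]

#: Magnitude-background correction of the NEMA single-image SNR method:
#: the SD of Rayleigh-distributed background magnitude underestimates the
#: underlying Gaussian noise SD by this factor.
RAYLEIGH_CORRECTION = 0.66


@dataclass(frozen=True)
class AgreementReport:
    """Agreement between a reference and a test method on paired values."""

    slope: float
    intercept: float
    r2: float
    icc: float
    icc_model: str
    bias: float
    loa_lower: float
    loa_upper: float
    n: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r2 <= 1 + 1e-12:
            raise ValueError("Pearson R^2 must lie in [0, 1]")
        if not self.loa_lower - 1e-12 <= self.bias <= self.loa_upper + 1e-12:
            raise ValueError("bias must lie within the limits of agreement")

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "icc": self.icc,
            "icc_model": self.icc_model,
            "bland_altman": {
                "bias": self.bias,
                "loa_lower": self.loa_lower,
                "loa_upper": self.loa_upper,
            },
            "n": self.n,
        }


@dataclass(frozen=True)
class PhaseStatsReport:
    """Nonparametric statistics over a subjects x phases T2* table."""

    friedman_chi2: float
    friedman_dof: int
    friedman_p: float
    friedman_exact_fallback: bool
    pairwise_wilcoxon: pd.DataFrame  # columns: phase_a, phase_b, p_raw, p_holm
    mannwhitney: pd.DataFrame | None  # columns: contrast, u, p, stars
    spearman: pd.DataFrame | None  # columns: covariate, rho, p, strength, stars


def significance_stars(p: float) -> str:
    """Significance markers: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def spearman_strength(rho: float) -> str:
    """Verbal correlation strength for |rho|.

    Bins: very weak (0.00-0.19), weak (0.20-0.39), moderate (0.40-0.59),
    strong (0.60-0.79), very strong (0.80-1.00).
    """
    a = abs(rho)
    if a < 0.2:
        return "very weak"
    if a < 0.4:
        return "weak"
    if a < 0.6:
        return "moderate"
    if a < 0.8:
        return "strong"
    return "very strong"


def nema_snr(
    image: np.ndarray,
    signal_roi: np.ndarray,
    background_roi: np.ndarray,
    rayleigh_correction: float = RAYLEIGH_CORRECTION,
) -> float:
    """NEMA single-image SNR of a magnitude image.

    SNR = mean(signal ROI) / (SD(background ROI) / 0.66), where the 0.66
    factor converts the Rayleigh-distributed magnitude background SD into
    the underlying Gaussian noise SD.  The background ROI must lie in a
    signal-free region disjoint from the signal ROI.

    Returns ``inf`` when the background SD is zero (noiseless image).
    """
    image = np.asarray(image, dtype=float)
    sig = np.asarray(signal_roi, dtype=bool)
    bg = np.asarray(background_roi, dtype=bool)
    if np.any(sig & bg):
        raise ValueError("signal and background ROIs must be disjoint")
    if not sig.any() or not bg.any():
        raise ValueError("both ROIs must be non-empty")
    sd = float(image[bg].std(ddof=1))
    if sd == 0.0:
        warnings.warn("background SD is zero; SNR is infinite", RuntimeWarning, stacklevel=2)
        return float("inf")
    return float(image[sig].mean() / (sd / rayleigh_correction))


def _icc_two_way_absolute_single(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Delegates to pingouin's ICC table (imported lazily; it is a heavy
    import) and reads out the ICC2 row.
    """
    import pingouin as pg

    n = x.size
    df = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["reference", "binned"], n),
            "score": np.concatenate([x, y]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(
            data=df, targets="target", raters="rater", ratings="score"
        ).set_index("Type")
    for label in ("ICC2", "ICC(A,1)"):  # shrout-fleiss vs mcgraw-wong naming
        if label in table.index:
            return float(table.loc[label, "ICC"])
    raise RuntimeError("ICC(2,1) row not found in the ICC table")


def method_agreement(x: np.ndarray, y: np.ndarray) -> AgreementReport:
    """Agreement between reference (``x``) and binned (``y``) T2* values.

    Computes ordinary least-squares slope/intercept, Pearson R^2, the
    intraclass correlation coefficient (two-way, absolute agreement,
    single measures), and Bland-Altman bias with 95% limits of agreement
    (bias +/- 1.96 * SD of the paired differences).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: regression undefined")

    reg = stats.linregress(x, y)
    r2 = float(reg.rvalue**2)
    icc = _icc_two_way_absolute_single(x, y)

    d = y - x
    bias = float(d.mean())
    sd_d = float(d.std(ddof=1))
    return AgreementReport(
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r2=r2,
        icc=icc,
        icc_model="two-way random, absolute agreement, single measures (ICC2)",
        bias=bias,
        loa_lower=bias - 1.96 * sd_d,
        loa_upper=bias + 1.96 * sd_d,
        n=int(n),
    )


def _pairwise_wilcoxon(table: pd.DataFrame) -> pd.DataFrame:
    """Holm-adjusted Wilcoxon signed-rank tests for every phase pair."""
    from statsmodels.stats.multitest import multipletests

    pairs = list(combinations(table.columns, 2))
    raw = []
    for a, b in pairs:
        d = table[a].to_numpy() - table[b].to_numpy()
        if np.all(d == 0):
            raw.append(1.0)
            continue
        res = stats.wilcoxon(table[a], table[b])
        raw.append(float(res.pvalue))
    holm = multipletests(raw, method="holm")[1] if raw else np.array([])
    return pd.DataFrame(
        {
            "phase_a": [a for a, _ in pairs],
            "phase_b": [b for _, b in pairs],
            "p_raw": raw,
            "p_holm": holm,
        }
    )


def _mannwhitney(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    levels = sorted(pd.unique(groups))
    rows = []
    for ga, gb in combinations(levels, 2):
        a = values[groups == ga].to_numpy()
        b = values[groups == gb].to_numpy()
        pooled = np.concatenate([a, b])
        has_ties = np.unique(pooled).size < pooled.size
        # exact null distribution for small cohorts; normal approximation
        # with tie correction otherwise
        method = "exact" if (max(a.size, b.size) <= 10 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append(
            {
                "contrast": f"{ga} vs {gb}",
                "u": float(res.statistic),
                "p": float(res.pvalue),
                "stars": significance_stars(float(res.pvalue)),
            }
        )
    return pd.DataFrame(rows)


def phase_stats(
    table: pd.DataFrame,
    groups: pd.Series | None = None,
    covariates: pd.DataFrame | None = None,
) -> PhaseStatsReport:
    """Nonparametric phase and group statistics on a per-subject table.

    Parameters
    ----------
    table:
        Complete subjects x phases table of T2* values (no missing phases,
        >= 2 subjects, >= 3 phases).
    groups:
        Optional group label per subject (e.g. genotype) for Mann-Whitney
        U comparisons of cycle-averaged T2*.
    covariates:
        Optional per-subject covariates (e.g. LV mass) for Spearman
        correlations against cycle-averaged T2*.
    """
    if table.isna().any().any():
        raise ValueError("the phase table must be complete (no missing phases)")
    if table.shape[0] < 2 or table.shape[1] < 3:
        raise ValueError("need >= 2 subjects and >= 3 phases")

    per_row_flat = (table.max(axis=1) - table.min(axis=1)) == 0
    if per_row_flat.all():
        # Ties-only degenerate input: every subject is constant across
        # phases, so the rank statistic is exactly zero.
        chi2, p, fallback = 0.0, 1.0, True
    else:
        res = stats.friedmanchisquare(*[table[c] for c in table.columns])
        chi2, p, fallback = float(res.statistic), float(res.pvalue), False
    dof = table.shape[1] - 1

    wilcoxon = _pairwise_wilcoxon(table)
    cycle_mean = table.mean(axis=1)

    mwu = None
    if groups is not None:
        groups = pd.Series(groups, index=table.index)
        mwu = _mannwhitney(cycle_mean, groups)

    spearman = None
    if covariates is not None:
        rows = []
        for name in covariates.columns:
            rho, pv = stats.spearmanr(cycle_mean, covariates[name])
            rows.append(
                {
                    "covariate": name,
                    "rho": float(rho),
                    "p": float(pv),
                    "strength": spearman_strength(float(rho)),
                    "stars": significance_stars(float(pv)),
                }
            )
        spearman = pd.DataFrame(rows)

    return PhaseStatsReport(
        friedman_chi2=chi2,
        friedman_dof=dof,
        friedman_p=p,
        friedman_exact_fallback=fallback,
        pairwise_wilcoxon=wilcoxon,
        mannwhitney=mwu,
        spearman=spearman,
    )
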