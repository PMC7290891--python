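"""Inter-method agreement statistics and supporting tests.

Two software tools measuring the same biomarker on the same patients are
compared on *relative* differences, because tumour-burden values span
orders of magnitude and the measurement error scales with the value:

    d_i = (A_i − B_i) / ((A_i + B_i) / 2) × 100   [percent of pair mean]

Bland–Altman summaries follow: bias = mean(d), limits of agreement
bias ± 1.96 × SD(d), and the repeatability coefficient RC = 1.96 × SD(d) —
the magnitude below which ~95% of between-method relative differences are
expected to fall when differences are roughly Gaussian.  Sample SD (n − 1
denominator) is used throughout.  Pairs whose relative difference falls
outside the limits of agreement are flagged as outliers; the limits are
computed from all pairs, with no iterative exclusion.

The module also wraps the rank-based tests used around such comparisons
(Spearman correlation, Wilcoxon signed-rank, Shapiro–Wilk normality) and a
paired-difference power analysis on the noncentral t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AgreementResult",
    "PowerSpec",
    "relative_differences",
    "bland_altman",
    "repeatability_coefficient",
    "spearman_rho",
    "wilcoxon_signed_rank",
    "shapiro_wilk",
    "paired_t_power",
    "required_sample_size",
]


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman summary of one paired-method comparison (percent units)."""

    n_pairs: int
    relative_difference_pct: np.ndarray  # y-axis of the Bland–Altman plot
    pair_mean: np.ndarray                # x-axis: (A + B) / 2, original units
    bias_pct: float
    sd_pct: float
    loa_low_pct: float
    loa_high_pct: float
    rc_pct: float
    outlier: np.ndarray                  # |d − bias| > 1.96 × SD

    @property
    def n_outliers(self) -> int:
        return int(self.outlier.sum())


def relative_differences(
    values_a: np.ndarray,
    values_b: np.ndarray,
    denominator: str = "mean",
) -> np.ndarray:
    """Per-pair relative difference in percent.

    ``denominator="mean"`` (default) uses the pair mean — the standard
    Bland–Altman ratio variant; ``denominator="a"`` expresses the difference
    as percent of method A, available for sensitivity checks.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values_A and values_B must be equal-length 1-D arrays")
    if denominator == "mean":
        denom = (a + b) / 2.0
    elif denominator == "a":
        denom = a
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if np.any(denom == 0):
        raise ValueError("relative difference undefined: a pair has zero denominator")
    return (a - b) / denom * 100.0


def bland_altman(
    values_a: np.ndarray,
    values_b: np.ndarray,
    denominator: str = "mean",
) -> AgreementResult:
    """Bland–Altman analysis on relative differences of two paired methods."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.ndim != 1 or a.shape != b.shape:
        raise ValueError("values_A and values_B must be equal-length 1-D arrays")
    if a.size < 2:
        raise ValueError("Bland–Altman analysis needs at least 2 pairs")
    d = relative_differences(a, b, denominator=denominator)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half_width = 1.96 * sd
    return AgreementResult(
        n_pairs=int(a.size),
        relative_difference_pct=d,
        pair_mean=(a + b) / 2.0,
        bias_pct=bias,
        sd_pct=sd,
        loa_low_pct=bias - half_width,
        loa_high_pct=bias + half_width,
        rc_pct=half_width,
        outlier=np.abs(d - bias) > half_width,
    )


def repeatability_coefficient(rel_diffs: np.ndarray) -> float:
    """RC = 1.96 × sample SD of the relative differences (n ≥ 2)."""
    d = np.asarray(rel_diffs, dtype=np.float64)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("repeatability coefficient needs at least 2 differences")
    return 1.96 * float(d.std(ddof=1))


def spearman_rho(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p.

    A constant input vector has no rank ordering, so the coefficient is
    undefined and an error is raised.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("spearman_rho needs equal-length 1-D arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; midranks handle ties; the exact null
    distribution is used for n ≤ 25 zero-free-and-tie-free pairs, otherwise
    the normal approximation with continuity correction.  All-zero
    differences leave nothing to test and raise an error.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; Wilcoxon test undefined")
    method = "exact" if (d.size <= 25 and np.unique(np.abs(d)).size == d.size) else "approx"
    res = stats.wilcoxon(d, method=method, correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


def shapiro_wilk(x: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk W statistic and p-value for normality."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("Shapiro–Wilk needs a 1-D sample with n >= 3")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PowerSpec:
    """Settings for the paired-difference sample-size computation.

    ``effect_size_dz`` is Cohen's d_z: mean paired difference divided by the
    SD of the differences.  Defaults correspond to ruling out a large
    between-method effect (0.7) at 80% power, two-sided α = 0.05.
    """

    effect_size_dz: float = 0.7
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.effect_size_dz <= 0:
            raise ValueError("effect size d_z must be positive")
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")


def paired_t_power(n: int, dz: float, alpha: float = 0.05) -> float:
    """Power of the two-sided one-sample/paired t test at sample size n.

    With noncentrality δ = d_z·√n and df = n − 1, power is
    P(|T'| > t_{1−α/2, n−1}) under the noncentral t distribution.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    df = n - 1
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    nc = dz * np.sqrt(n)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def required_sample_size(spec: PowerSpec = PowerSpec(), max_n: int = 100_000) -> int:
    """Smallest n at which the paired t test reaches the requested power."""
    for n in range(2, max_n + 1):
        if paired_t_power(n, spec.effect_size_dz, spec.alpha) >= spec.power:
            return n
    raise ValueError(f"required sample size exceeds {max_n}")
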