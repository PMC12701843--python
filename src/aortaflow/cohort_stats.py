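"""Two-group cohort statistics with a normality gate.

Continuous metrics are summarised as mean +/- SD and median with
quartiles.  Group contrasts follow the gated convention used in clinical
cohort reporting: Shapiro-Wilk normality per group; a two-sided Student
t test when both groups are compatible with normality, a two-sided
Mann-Whitney U test otherwise.  The Mann-Whitney p value is exact (full
enumeration) for small untied samples and uses the normal approximation
with tie and continuity correction otherwise.  No multiple-testing
correction is applied: p values are reported per metric, as in the
clinical tables this layer emulates.

Box-and-whisker descriptors follow the Tukey convention: quartiles by
linear interpolation, 1.5 x IQR outlier fences, whiskers at the extreme
non-outliers, with the mean reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "BoxStats",
    "normality_gate",
    "compare_groups",
    "box_stats",
    "percent_increment",
]


@dataclass(frozen=True)
class NormalityResult:
    statistic: float  # Shapiro-Wilk W
    p_value: float
    normal: bool  # p >= alpha


def normality_gate(sample, alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk normality assessment of one sample.

    ``normal`` iff the Shapiro-Wilk p value is >= alpha.  Requires
    3 <= n <= 5000 and non-zero variance.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise ValueError("normality test requires at least 3 observations")
    if len(x) > 5000:
        raise ValueError("Shapiro-Wilk is unreliable above n = 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample has no defined normality")
    w, p = sps.shapiro(x)
    return NormalityResult(statistic=float(w), p_value=float(p), normal=p >= alpha)


@dataclass(frozen=True)
class GroupComparison:
    """Two-group contrast for one metric."""

    metric: str
    labels: tuple[str, str]
    n: tuple[int, int]
    mean: tuple[float, float]
    sd: tuple[float, float]
    median: tuple[float, float]
    q1: tuple[float, float]
    q3: tuple[float, float]
    test: str  # "t_test" | "mann_whitney"
    statistic: float
    p_value: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small untied samples, normal
    approximation with tie + continuity correction otherwise."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    x,
    y,
    alpha: float = 0.05,
    metric: str = "",
    labels: tuple[str, str] = ("a", "b"),
    force_test: str | None = None,
) -> GroupComparison:
    """Normality-gated two-group comparison.

    If both groups pass the Shapiro-Wilk gate at ``alpha`` the contrast is
    a two-sided two-sample Student t test; if either fails, a two-sided
    Mann-Whitney U test.  ``force_test`` ("t_test" / "mann_whitney")
    bypasses the gate, for calibration studies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("both groups need at least 3 observations")

    if force_test is None:
        try:
            both_normal = normality_gate(x, alpha).normal and normality_gate(y, alpha).normal
        except ValueError:  # constant sample: no normality, take the rank path
            both_normal = False
        test = "t_test" if both_normal else "mann_whitney"
    else:
        if force_test not in ("t_test", "mann_whitney"):
            raise ValueError(f"unknown test: {force_test!r}")
        test = force_test

    if test == "t_test":
        res = sps.ttest_ind(x, y, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        stat, p = _mann_whitney(x, y)

    return GroupComparison(
        metric=metric,
        labels=labels,
        n=(len(x), len(y)),
        mean=(float(x.mean()), float(y.mean())),
        sd=(float(x.std(ddof=1)), float(y.std(ddof=1))),
        median=(float(np.median(x)), float(np.median(y))),
        q1=(float(np.percentile(x, 25)), float(np.percentile(y, 25))),
        q3=(float(np.percentile(x, 75)), float(np.percentile(y, 75))),
        test=test,
        statistic=stat,
        p_value=p,
        alpha=alpha,
    )


@dataclass(frozen=True)
class BoxStats:
    """Box-and-whisker descriptors of one sample (Tukey convention)."""

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]
    mean: float


def box_stats(sample) -> BoxStats:
    """Quartiles, Tukey 1.5 x IQR fences, whiskers at extreme non-outliers.

    Quartiles use linear interpolation between order statistics.  The mean
    is reported separately (the 'X' marker of clinical box plots).
    Whiskers are clamped to the box, so on degenerate small samples (an
    interpolated quartile beyond every non-outlier) the ordering
    whisker_low <= q1 <= median <= q3 <= whisker_high still holds.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = x[(x < lo_fence) | (x > hi_fence)]
    return BoxStats(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_low=float(min(inliers.min(), q1)),
        whisker_high=float(max(inliers.max(), q3)),
        outliers=tuple(sorted(float(v) for v in outliers)),
        mean=float(x.mean()),
    )


def percent_increment(median_a: float, median_b: float) -> float:
    """Percent by which a exceeds b: ``100 (a - b) / b``."""
    if median_b == 0:
        raise ValueError("reference median must be non-zero")
    return 100.0 * (median_a - median_b) / median_b
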