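"""Condition comparisons: rank-sum tests and box-plot summaries.

Conditions are compared with the two-sided Wilcoxon rank-sum
(Mann-Whitney U) test: exact enumeration for small tie-free samples
(``n_x + n_y <= 16``), otherwise the normal approximation with tie and
continuity corrections.  Significance stars follow the conventional
0.05 / 0.01 / 0.001 thresholds.

Box summaries use quartiles by linear interpolation.  Two whisker modes are
provided: the default Tukey convention (whiskers at the most extreme values
inside 1.5 IQR fences, points beyond flagged as outliers) and a ``minmax``
mode with whiskers at the sample extremes (in which case no point can lie
outside them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return ""


@dataclass(frozen=True)
class TestResult:
    u_statistic: float
    p_two_sided: float
    n_x: int
    n_y: int
    method: str  # "exact" | "normal-approximation"
    stars: str


@dataclass(frozen=True)
class BoxSummary:
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def ranksum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney U test.

    Exact enumeration when ``n_x + n_y <= 16`` and the pooled sample is
    tie-free; otherwise the normal approximation with continuity and tie
    corrections.  The p-value depends on the data only through pooled
    ranks, so it is invariant under strictly monotone transforms.
    """
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    if xa.size + ya.size <= 16 and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(xa, ya, alternative="two-sided", method="exact")
    else:
        method = "normal-approximation"
        res = stats.mannwhitneyu(
            xa, ya, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    p = float(min(res.pvalue, 1.0))
    return TestResult(
        u_statistic=float(res.statistic),
        p_two_sided=p,
        n_x=int(xa.size),
        n_y=int(ya.size),
        method=method,
        stars=significance_stars(p),
    )


def boxplot_stats(values: Sequence[float], whiskers: str = "tukey") -> BoxSummary:
    """Five-number box summary with Tukey or min-max whiskers."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size == 0:
        raise ValueError("need at least one value")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    if whiskers == "minmax":
        return BoxSummary(
            median=float(med),
            q25=float(q25),
            q75=float(q75),
            whisker_low=float(v[0]),
            whisker_high=float(v[-1]),
            outliers=(),
        )
    if whiskers != "tukey":
        raise ValueError("whiskers must be 'tukey' or 'minmax'")
    iqr = q75 - q25
    lo_fence = q25 - 1.5 * iqr
    hi_fence = q75 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(float(o) for o in v[(v < lo_fence) | (v > hi_fence)])
    return BoxSummary(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_low=float(inside[0]),
        whisker_high=float(inside[-1]),
        outliers=outliers,
    )


def per_culture_agreement(
    results: Sequence[TestResult], alpha: float = 0.05
) -> bool:
    """True when every culture's test agrees (all significant at ``alpha``).

    Replicates the reporting convention of displaying a significance level
    only when the per-culture tests all show it.
    """
    if not results:
        raise ValueError("need at least one test result")
    return all(r.p_two_sided < alpha for r in results)
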