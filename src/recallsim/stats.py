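"""Scenario-comparison statistics.

Three tests compare a risk-stratified scenario with its conventional partner:

* Levene's test (mean-centered by default) for equality of the daily-recall
  variances;
* the Wilcoxon signed-rank test for paired per-day outcomes (days are paired
  by replication seed and day index, which is meaningful because paired
  scenarios run on common random numbers);
* the Wilcoxon rank-sum test for unpaired per-patient outcomes (waiting
  times), computed through its Mann-Whitney U equivalence with midranks and
  tie-corrected, continuity-corrected normal approximation for large samples
  and exact enumeration for tiny ones.

All p-values are two-sided.  Degenerate inputs (identical groups, or all
paired differences zero) return p = 1 by convention with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ComparisonReport:
    outcome: str
    scenario_a: str
    scenario_b: str
    test: str  # "levene" | "signed_rank" | "rank_sum"
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def levene(x, y, center: str = "mean") -> tuple[float, float]:
    """Levene's W for equality of two variances; F-tail p-value.

    ``center="median"`` switches to the Brown-Forsythe variant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each series needs at least 2 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        warnings.warn("degenerate (constant) series; returning p = 1")
        return 0.0, 1.0
    w, p = sps.levene(x, y, center=center)
    return float(w), float(p)


def signed_rank(x, y) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired series (two-sided).

    Zero differences are dropped (Wilcoxon's original treatment); the normal
    approximation with continuity correction is used for n > 25, exact
    enumeration below.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    d = x - y
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; returning p = 1")
        return 0.0, 1.0
    n_nonzero = int(np.count_nonzero(d))
    method = "exact" if n_nonzero <= 25 and not _has_tied_magnitudes(d) else "approx"
    res = sps.wilcoxon(x, y, zero_method="wilcox", correction=True, method=method)
    return float(res.statistic), float(res.pvalue)


def _has_tied_magnitudes(d: np.ndarray) -> bool:
    mags = np.abs(d[d != 0])
    return len(np.unique(mags)) < len(mags)


def rank_sum(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both series must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("identical constant series; returning p = 1")
        return float(len(x) * len(y) / 2.0), 1.0
    small = len(x) <= 10 and len(y) <= 10 and len(np.unique(pooled)) == len(pooled)
    method = "exact" if small else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare(
    outcome: str,
    scenario_a: str,
    x,
    scenario_b: str,
    y,
    test: str,
) -> ComparisonReport:
    fn = {"levene": levene, "signed_rank": signed_rank, "rank_sum": rank_sum}[test]
    stat, p = fn(x, y)
    return ComparisonReport(
        outcome=outcome,
        scenario_a=scenario_a,
        scenario_b=scenario_b,
        test=test,
        statistic=stat,
        p_value=p,
    )
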