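"""Nonparametric tests used for paired image metrics and residence times.

Image parameters before/after fixation are paired per cell (Wilcoxon
signed-rank); residence times of two proteins come from independent groups
of cells (Wilcoxon rank-sum / Mann-Whitney U).  Both delegate to
scipy.stats, with exact small-sample p-values and a continuity-corrected
normal approximation for larger samples.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import stats

__all__ = ["TestResult", "wilcoxon_signed_rank", "wilcoxon_rank_sum"]

EXACT_N_MAX = 25  # exact signed-rank null enumeration up to here


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str


def wilcoxon_signed_rank(differences) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (standard convention); the null is
    enumerated exactly up to n = 25 and approximated normally (with
    continuity correction) above.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; test undefined")
    if d.size < 5:
        warnings.warn(f"only {d.size} nonzero pairs; signed-rank p is coarse")
    method = "exact" if d.size <= EXACT_N_MAX else "approx"
    res = stats.wilcoxon(
        d, alternative="two-sided", correction=(method == "approx"), method=method
    )
    return TestResult(float(res.statistic), float(res.pvalue), int(d.size), method)


def wilcoxon_rank_sum(group_a, group_b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test for two groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult(float(res.statistic), float(res.pvalue), int(a.size + b.size), "auto")
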