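"""Shared statistical primitives (rank-sum and unpaired t tests)."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

#: significance level used throughout the analysis
ALPHA = 0.05


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two independent samples.

    Exact enumeration (via the Mann–Whitney U distribution) when both groups
    have <= 10 observations, otherwise the tie-corrected, continuity-corrected
    normal approximation.  Degenerate data in which every observation of both
    groups is identical returns p = 1 (no evidence of a shift).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("rank-sum test needs >= 2 observations per group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    method = "exact" if max(x.size, y.size) <= 10 and not _has_ties(pooled) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def unpaired_t_test(a, b) -> tuple[float, float]:
    """Two-sample unpaired Student t-test (pooled variance, two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
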