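"""Exact unpaired two-sample rank-sum testing.

Scenario comparisons use the unpaired two-sample Wilcoxon rank-sum
(Mann-Whitney) test. With 10 replicates per scenario cell the samples are
small, so exactness matters: for a combined size of at most 20 the p-value is
computed exactly — via the classical rank-sum null distribution when there
are no ties, and by full enumeration of the permutation distribution of the
rank statistic (midranks) when ties are present, where the classical
distribution is no longer valid. Larger samples fall back to the
tie-corrected normal approximation.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

__all__ = ["rank_sum_test"]

_EXACT_LIMIT = 20


def rank_sum_test(a, b) -> float:
    """Two-sided rank-sum p-value for independent samples *a* and *b*.

    Returns 1.0 for the degenerate case where every value in both samples is
    identical (there is no evidence of any difference).

    Raises
    ------
    ValueError
        If either sample has fewer than two observations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("rank_sum_test requires at least two observations per sample")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    n, m = a.size, b.size
    has_ties = np.unique(pooled).size < pooled.size
    if n + m <= _EXACT_LIMIT:
        if not has_ties:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            return float(res.pvalue)
        return _exact_permutation_p(pooled, n)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _exact_permutation_p(pooled: np.ndarray, n: int) -> float:
    """Enumerate all C(n+m, n) group assignments of the midrank statistic.

    The statistic is the first sample's rank sum centred at its null mean;
    the two-sided p-value counts assignments at least as extreme as observed
    (with a small tolerance against floating-point rank arithmetic).
    """
    N = pooled.size
    ranks = stats.rankdata(pooled)  # midranks under ties
    observed = abs(ranks[:n].sum() - n * (N + 1) / 2.0)
    count = 0
    for idx in combinations(range(N), n):
        t = abs(ranks[list(idx)].sum() - n * (N + 1) / 2.0)
        if t >= observed - 1e-9:
            count += 1
    return count / comb(N, n)
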