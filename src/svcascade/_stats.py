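"""Shared statistical primitives: exact 2x2 test, BH adjustment, Welch t-test.

The two-sided Fisher exact test is computed with exact integer arithmetic
(binomial-coefficient numerators over a common denominator), so inclusion of
tied point masses is decided exactly rather than through a floating-point
epsilon.  For the pooled-count tables this package tests (margins up to a few
hundred) this is both exact and fast.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["fisher_exact_two_sided", "bh_adjust", "welch_t"]


@lru_cache(maxsize=200_000)
def _table_numerators(total_a: int, total_b: int, meth_sum: int) -> tuple[int, ...]:
    """Numerators C(total_a,k)*C(total_b,meth_sum-k) over the support of k."""
    k_min = max(0, meth_sum - total_b)
    k_max = min(total_a, meth_sum)
    return tuple(comb(total_a, k) * comb(total_b, meth_sum - k) for k in range(k_min, k_max + 1))


def fisher_exact_two_sided(meth_a: int, total_a: int, meth_b: int, total_b: int) -> float:
    """Two-sided Fisher exact p-value for the 2x2 table

        [[meth_a, total_a - meth_a],
         [meth_b, total_b - meth_b]]

    summing the hypergeometric point masses that are <= the observed mass,
    with the tie comparison done on exact integers.
    """
    for name, value in (("meth_a", meth_a), ("total_a", total_a),
                        ("meth_b", meth_b), ("total_b", total_b)):
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")
    if meth_a > total_a or meth_b > total_b:
        raise ValueError("methylated count exceeds total count")
    if total_a == 0 and total_b == 0:
        raise ValueError("both totals are zero: test undefined")

    meth_sum = meth_a + meth_b
    nums = _table_numerators(total_a, total_b, meth_sum)
    k_min = max(0, meth_sum - total_b)
    observed = nums[meth_a - k_min]
    numerator = sum(n for n in nums if n <= observed)
    denominator = comb(total_a + total_b, meth_sum)
    return numerator / denominator


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]


def welch_t(x, y) -> tuple[float, float]:
    """Welch two-tailed t-test; returns (t, p).  Degenerate inputs give (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        return float("nan"), float("nan")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)
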