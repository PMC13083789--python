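"""Replicate-level nonparametric tests and significance annotation.

Flow-sorting experiments compare compositions across a handful of
biological replicates (independent differentiations, typically n = 3-4),
so the tests of choice are exact nonparametric ones: the Wilcoxon
matched-pairs signed-rank test for paired data and the Mann-Whitney U test
for unpaired data.  At these sample sizes asymptotic p-values are
unreliable, so exact null distributions are computed by the classical
shift-convolution recursion:

* Wilcoxon: exact for n <= 25 pairs (after zero-difference removal, zeros
  dropped, ties mid-ranked), enumerating the 2^n sign assignments through
  a polynomial-product DP over doubled (hence integral) ranks;
* Mann-Whitney: exact for n1 + n2 <= 16 without ties, counting rank-sum
  subsets by DP; tie-corrected normal approximation otherwise (with
  continuity correction).

Two-sided p-values are twice the smaller tail, capped at 1.  Significance
stars follow the conventional thresholds: * p<0.05, ** p<0.01, *** p<0.001,
**** p<0.0001, else "ns".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["TestResult", "wilcoxon_signed_rank", "mann_whitney", "stars"]

_WILCOXON_EXACT_MAX_N = 25
_MANN_WHITNEY_EXACT_MAX_N = 16


@dataclass(frozen=True)
class TestResult:
    """Outcome of one two-sided nonparametric comparison."""

    method: Literal["wilcoxon_signed_rank", "mann_whitney"]
    statistic: float
    p_value: float
    n: tuple[int, ...]
    stars: str
    exact: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def stars(p_value: float) -> str:
    """Asterisk annotation for a p-value."""
    if not (0.0 <= p_value <= 1.0):
        raise ValueError(f"p-value must lie in [0, 1], got {p_value}")
    if p_value < 0.0001:
        return "****"
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Wilcoxon matched-pairs signed-rank test
# ---------------------------------------------------------------------------

def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Counts of the doubled W+ statistic over all 2^n sign assignments.

    ``double_ranks`` are 2x the (possibly mid-) ranks, hence integers;
    entry ``k`` of the result counts assignments with 2*W+ == k.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped; absolute differences are mid-ranked.
    Exact p by enumeration of sign assignments for up to 25 nonzero pairs,
    tie-corrected normal approximation above.  If every difference is
    zero the result is degenerate with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1-D samples with n >= 1")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult(
            method="wilcoxon_signed_rank", statistic=0.0, p_value=1.0,
            n=(x.size,), stars=stars(1.0), exact=True, degenerate=True,
        )
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= _WILCOXON_EXACT_MAX_N:
        double_ranks = np.rint(2.0 * ranks).astype(np.int64)
        counts = _signed_rank_distribution(double_ranks)
        total = counts.sum()  # 2**n
        w2 = int(np.rint(2.0 * w_plus))
        cdf = counts[: w2 + 1].sum() / total
        sf = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        exact = True
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w_plus - mean) / np.sqrt(var)
        p = min(1.0, 2.0 * float(norm.sf(abs(z))))
        exact = False
    return TestResult(
        method="wilcoxon_signed_rank", statistic=w_plus, p_value=p,
        n=(int(n),), stars=stars(p), exact=exact,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U test
# ---------------------------------------------------------------------------

def _rank_sum_distribution(n1: int, n: int) -> np.ndarray:
    """Counts of rank-sums of n1-subsets of ranks 1..n (no ties).

    DP over the C(n, n1) labelings; entry ``s`` counts subsets whose rank
    sum is ``s``.
    """
    max_sum = n1 * n
    # counts[k][s]: subsets of size k with rank-sum s, built rank by rank
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            counts[k, r:] += counts[k - 1, : max_sum + 1 - r]
    return counts[n1]


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test (statistic U1, for the first sample).

    Exact p by enumeration of rank labelings when n1 + n2 <= 16 and the
    pooled sample is tie-free; tie-corrected normal approximation with
    continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size < 1 or y.size < 1:
        raise ValueError("x and y must be non-empty 1-D samples")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size

    if n1 + n2 <= _MANN_WHITNEY_EXACT_MAX_N and not has_ties:
        dist = _rank_sum_distribution(n1, n1 + n2)
        total = dist.sum()  # C(n1+n2, n1)
        s = int(np.rint(r1))
        cdf = dist[: s + 1].sum() / total
        sf = dist[s:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        exact = True
    else:
        mean = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var == 0.0:
            p, exact = 1.0, False
        else:
            num = max(abs(u1 - mean) - 0.5, 0.0)  # continuity correction
            z = num / np.sqrt(var)
            p = min(1.0, 2.0 * float(norm.sf(z)))
            exact = False
    return TestResult(
        method="mann_whitney", statistic=float(u1), p_value=p,
        n=(int(n1), int(n2)), stars=stars(p), exact=exact,
    )
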