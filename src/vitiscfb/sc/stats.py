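"""Wilcoxon rank-sum test used for marker and DEG calling.

Exact p-values are computed by enumerating the null distribution of the
rank-sum statistic (dynamic programming over k-subsets of ranks) whenever
the smaller group has at most 8 observations and there are no ties;
otherwise a normal approximation with tie-corrected variance, continuity
correction, and an Edgeworth kurtosis term is used (the rank-sum null is
platykurtic, and the plain normal tail is visibly off at small-to-moderate
group sizes).  scipy's implementation is deliberately not called here: it
serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["wilcoxon_rank_sum", "rank_sum_null_distribution"]

_EXACT_MAX = 8


def rank_sum_null_distribution(n: int, m: int) -> np.ndarray:
    """Counts of k-subsets of {1..n+m} by sum, for the group of size ``n``.

    ``out[s]`` is the number of ways the n ranks of group one can sum to s
    under the null (all C(n+m, n) assignments equally likely).
    """
    N = n + m
    max_sum = N * (N + 1) // 2
    # dp[k][s]: number of k-subsets of {1..i} summing to s, built iteratively
    dp = np.zeros((n + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for i in range(1, N + 1):
        for k in range(min(i, n), 0, -1):
            dp[k, i:] += dp[k - 1, : max_sum + 1 - i]
    return dp[n]


def wilcoxon_rank_sum(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the sum of (average, for ties) ranks of
    ``x`` in the pooled sample.  ``method`` is ``"auto"`` (exact when the
    smaller group has <= 8 observations and there are no ties, otherwise
    the corrected normal approximation), ``"exact"`` (enumeration; ties
    not supported) or ``"approx"``.
    """
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:n].sum())
    N = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if method == "exact" and has_ties:
        raise ValueError("exact enumeration requires tie-free data")
    use_exact = (
        method == "exact"
        or (method == "auto" and min(n, m) <= _EXACT_MAX and not has_ties)
    )
    if use_exact:
        dist = rank_sum_null_distribution(n, m)
        total = dist.sum()
        wi = int(round(w))
        lower = dist[: wi + 1].sum() / total
        upper = dist[wi:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return w, float(p)

    mu = n * (N + 1) / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    sd = np.sqrt(var)
    # excess kurtosis of the tie-free rank-sum null (platykurtic)
    g2 = -6.0 * (n * n + m * m + n * m + n + m) / (5.0 * n * m * (N + 1))

    def edgeworth_cdf(x: float) -> float:
        val = norm.cdf(x) - norm.pdf(x) * (g2 / 24.0) * (x**3 - 3.0 * x)
        return min(max(val, 0.0), 1.0)

    lower = edgeworth_cdf((w + 0.5 - mu) / sd)   # P(W <= w), continuity-corrected
    upper = 1.0 - edgeworth_cdf((w - 0.5 - mu) / sd)  # P(W >= w)
    p = min(1.0, 2.0 * min(lower, upper))
    return w, p
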