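"""Independent brute-force oracles for the exact statistical tests.

These deliberately share no code with somatrio.stats: Fisher probabilities
come from exact rational hypergeometric enumeration, rank-sum tail counts
from a dynamic program over rank subsets, and signed-rank tails from
enumeration of all sign vectors.
"""

import math
from fractions import Fraction

import numpy as np
from scipy.stats import rankdata


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Point-probability-rule two-sided p by exact rational enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d
    k_min, k_max = max(0, r1 + c1 - n), min(r1, c1)

    def pmf(k: int) -> Fraction:
        return Fraction(math.comb(c1, k) * math.comb(n - c1, r1 - k), math.comb(n, r1))

    if k_min == k_max:
        return 1.0
    p_obs = pmf(a)
    return float(sum(p for k in range(k_min, k_max + 1) if (p := pmf(k)) <= p_obs))


def ranksum_oracle(x, y, alternative: str) -> float:
    """Exact tail probability of the rank sum of x by subset-sum counting."""
    n, m = len(x), len(y)
    total_n = n + m
    pooled = list(x) + list(y)
    order = sorted(range(total_n), key=lambda i: pooled[i])
    ranks = [0] * total_n
    for r, i in enumerate(order):
        ranks[i] = r + 1
    w = sum(ranks[:n])
    max_sum = total_n * (total_n + 1) // 2
    dp = [[0] * (max_sum + 1) for _ in range(n + 1)]
    dp[0][0] = 1
    for r in range(1, total_n + 1):
        for k in range(min(r, n), 0, -1):
            row, prev = dp[k], dp[k - 1]
            for s in range(max_sum, r - 1, -1):
                row[s] += prev[s - r]
    total = math.comb(total_n, n)
    if alternative == "less":
        count = sum(dp[n][s] for s in range(w + 1))
    else:
        count = sum(dp[n][s] for s in range(w, max_sum + 1))
    return count / total


def signed_rank_oracle(x, mu: float, alternative: str) -> float:
    """Exact tail probability of W+ by enumeration of all 2^n sign vectors."""
    d = np.asarray(x, dtype=float) - mu
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    if alternative == "less":
        return float(np.count_nonzero(sums <= w + 1e-9)) / sums.size
    return float(np.count_nonzero(sums >= w - 1e-9)) / sums.size
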