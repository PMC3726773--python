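"""Exact small-sample tests used by the somatic false-positive filters.

Three tests back the filter criteria: Fisher's exact test on 2x2 allele-count
tables (tumor vs. normal allele-frequency change), the Wilcoxon rank-sum test
(read-end position bias of variant-supporting reads), and the Wilcoxon
signed-rank test against a fixed constant (mapping/base quality vetting of
variant-supporting reads against the phred floors 30 and 20).

Small samples dominate this workload -- the relevant populations are the
handful of variant-supporting reads at one site -- so each test carries an
exact enumeration branch below a size threshold and a tie-corrected,
continuity-corrected normal approximation above it.  The exact branches are
deliberately written so they can be checked against brute-force enumeration.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import hypergeom, norm, rankdata

Alternative = Literal["one_sided_less", "one_sided_greater", "two_sided"]

# exact enumeration kept under ~10^6 states
RANKSUM_EXACT_MAX_N = 20   # n + m
SIGNED_RANK_EXACT_MAX_N = 15


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    p_value: float
    method: Literal["exact", "normal_approx"]
    sidedness: Alternative

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _normalize_alternative(alternative: str) -> Alternative:
    alias = {
        "less": "one_sided_less",
        "greater": "one_sided_greater",
        "two-sided": "two_sided",
        "two_sided": "two_sided",
        "one_sided_less": "one_sided_less",
        "one_sided_greater": "one_sided_greater",
    }
    try:
        return alias[alternative]
    except KeyError:
        raise ValueError(f"unknown alternative: {alternative!r}") from None


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, alternative: str = "two_sided"
) -> TestResult:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    The two-sided p-value follows the point-probability rule: the sum of
    hypergeometric probabilities of every table with the observed margins
    whose probability does not exceed that of the observed table.  Exact for
    all table sizes.  Degenerate margins (an all-zero row or column) admit a
    single table and give p = 1.
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    n_total = a + b + c + d
    if n_total == 0:
        raise ValueError("empty 2x2 table")
    alt = _normalize_alternative(alternative)

    row1 = a + b
    col1 = a + c
    dist = hypergeom(n_total, col1, row1)  # cell (0,0) under fixed margins
    k_min = max(0, row1 + col1 - n_total)
    k_max = min(row1, col1)

    if alt == "one_sided_less":
        p = float(dist.cdf(a))
    elif alt == "one_sided_greater":
        p = float(dist.sf(a - 1))
    else:
        if k_min == k_max:  # degenerate margins: one admissible table
            p = 1.0
        else:
            support = np.arange(k_min, k_max + 1)
            pmf = dist.pmf(support)
            p_obs = dist.pmf(a)
            # relative tolerance guards against float noise on equal-probability tables
            p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    p = min(p, 1.0)

    odds_num = a * d
    odds_den = b * c
    statistic = math.inf if odds_den == 0 else odds_num / odds_den
    return TestResult(statistic=statistic, p_value=p, method="exact", sidedness=alt)


def _tie_correction_ranksum(all_values: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups."""
    _, counts = np.unique(all_values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def rank_sum_one_sided(
    x: Sequence[float], y: Sequence[float], alternative: str = "less"
) -> TestResult:
    """Wilcoxon/Mann-Whitney rank-sum test; statistic is the rank sum of ``x``.

    Exact by enumeration of all C(n+m, n) rank assignments when n + m does
    not exceed 20 and the pooled sample is tie-free; otherwise a normal
    approximation with mid-rank tie correction and continuity correction.
    ``alternative="less"`` tests whether ``x`` is stochastically smaller.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    alt = _normalize_alternative(alternative)

    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w_obs = float(ranks[:n].sum())
    has_ties = np.unique(pooled).size < pooled.size

    if n + m <= RANKSUM_EXACT_MAX_N and not has_ties:
        total = math.comb(n + m, n)
        all_ranks = range(1, n + m + 1)
        n_le = 0
        n_ge = 0
        for combo in itertools.combinations(all_ranks, n):
            w = sum(combo)
            if w <= w_obs + 1e-9:
                n_le += 1
            if w >= w_obs - 1e-9:
                n_ge += 1
        if alt == "one_sided_less":
            p = n_le / total
        elif alt == "one_sided_greater":
            p = n_ge / total
        else:
            p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return TestResult(statistic=w_obs, p_value=p, method="exact", sidedness=alt)

    big_n = n + m
    mean = n * (big_n + 1) / 2.0
    tie_term = _tie_correction_ranksum(pooled) / (big_n * (big_n - 1))
    var = n * m / 12.0 * ((big_n + 1) - tie_term)
    if var <= 0:  # all values identical
        return TestResult(statistic=w_obs, p_value=1.0, method="normal_approx", sidedness=alt)
    sd = math.sqrt(var)
    if alt == "one_sided_less":
        p = float(norm.cdf((w_obs - mean + 0.5) / sd))
    elif alt == "one_sided_greater":
        p = float(norm.sf((w_obs - mean - 0.5) / sd))
    else:
        z = (w_obs - mean) / sd
        p = float(2.0 * norm.sf(abs(z) - 0.5 / sd))
        p = min(p, 1.0)
    return TestResult(statistic=w_obs, p_value=p, method="normal_approx", sidedness=alt)


def _subset_sums(values: np.ndarray) -> np.ndarray:
    """All 2^n signed-subset sums (sum over elements assigned '+')."""
    sums = np.zeros(1)
    for v in values:
        sums = np.concatenate([sums, sums + v])
    return sums


def signed_rank_vs_constant(
    x: Sequence[float], mu: float, alternative: str = "less"
) -> TestResult:
    """One-sample Wilcoxon signed-rank test of ``x`` against the constant ``mu``.

    Values equal to ``mu`` are dropped (if all are dropped, p = 1 by
    convention).  The statistic is W+, the sum of mid-ranks of positive
    deviations.  Exact by enumeration of the 2^n sign assignments for
    n <= 15, otherwise a tie- and continuity-corrected normal approximation.
    """
    x = np.asarray(list(x), dtype=float)
    if x.size == 0:
        raise ValueError("sample must be non-empty")
    alt = _normalize_alternative(alternative)

    d = x - mu
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="exact", sidedness=alt)

    abs_ranks = rankdata(np.abs(d))
    w_plus = float(abs_ranks[d > 0].sum())

    if n <= SIGNED_RANK_EXACT_MAX_N:
        sums = _subset_sums(abs_ranks)
        total = sums.size
        p_le = float(np.count_nonzero(sums <= w_plus + 1e-9)) / total
        p_ge = float(np.count_nonzero(sums >= w_plus - 1e-9)) / total
        if alt == "one_sided_less":
            p = p_le
        elif alt == "one_sided_greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(statistic=w_plus, p_value=p, method="exact", sidedness=alt)

    mean = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return TestResult(statistic=w_plus, p_value=1.0, method="normal_approx", sidedness=alt)
    sd = math.sqrt(var)
    if alt == "one_sided_less":
        p = float(norm.cdf((w_plus - mean + 0.5) / sd))
    elif alt == "one_sided_greater":
        p = float(norm.sf((w_plus - mean - 0.5) / sd))
    else:
        z = (w_plus - mean) / sd
        p = min(1.0, float(2.0 * norm.sf(abs(z) - 0.5 / sd)))
    return TestResult(statistic=w_plus, p_value=p, method="normal_approx", sidedness=alt)
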