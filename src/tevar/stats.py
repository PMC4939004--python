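"""Shared statistical kernels.

Fisher's exact test and the hypergeometric tail are delegated to scipy;
Benjamini-Hochberg to statsmodels. The Wilcoxon rank-sum test is
implemented here because the contract is an exact permutation null for
small samples *including ties*, falling back to the tie- and
continuity-corrected normal approximation otherwise.
"""
from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_exact_two_sided",
    "wilcoxon_rank_sum",
    "hypergeom_p_ge",
    "bh_adjust",
]

EXACT_MAX_MIN_N = 8
EXACT_MAX_ARRANGEMENTS = comb(20, 10)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Two-sidedness by probability-mass summation: the p-value is the total
    probability of tables (with the observed margins) no more likely than
    the observed one. Degenerate margins give p = 1.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("negative cell count")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def hypergeom_p_ge(k: int, total: int, successes: int, drawn: int) -> float:
    """P(X >= k) for X ~ Hypergeom(total, successes, drawn)."""
    return float(sps.hypergeom.sf(k - 1, total, successes, drawn))


def _rank_sum_sigma(ranks: np.ndarray, n: int, m: int) -> float:
    """SD of the rank sum of an n-subset under the permutation null,
    with the tie correction."""
    N = n + m
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (N * (N - 1))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    return float(np.sqrt(var))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact permutation enumeration over all C(n+m, n) assignments when
    min(n, m) <= 8 and the arrangement count is at most C(20, 10); the
    exact path handles ties through midranks. Otherwise the normal
    approximation with tie and continuity corrections is used. The exact
    two-sided p counts arrangements with |W - E[W]| at least as large as
    observed (the permutation distribution of W is symmetric about E[W]).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:n].sum()
    e_w = n * (n + m + 1) / 2.0

    if np.unique(pooled).size == 1:
        return 1.0

    n_arr = comb(n + m, min(n, m))
    if min(n, m) <= EXACT_MAX_MIN_N and n_arr <= EXACT_MAX_ARRANGEMENTS:
        k = min(n, m)
        dev_obs = abs(w_obs - e_w)
        if k == m:  # enumerate the smaller sample's rank subsets
            e_small = m * (n + m + 1) / 2.0
            dev_obs = abs(ranks[n:].sum() - e_small)  # same by symmetry
            e_w = e_small
        hits = 0
        for idx in combinations(range(n + m), k):
            w = ranks[list(idx)].sum()
            if abs(w - e_w) >= dev_obs - 1e-9:
                hits += 1
        return hits / n_arr

    sigma = _rank_sum_sigma(ranks, n, m)
    if sigma == 0:
        return 1.0
    z = (abs(w_obs - e_w) - 0.5) / sigma
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
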