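"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately written as plain loops / exhaustive
enumeration, independent of the vectorized library code paths.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def brute_gsva_walk(z_col: np.ndarray, member: np.ndarray, tau: float = 1.0) -> float:
    """Step-by-step enrichment walk for a single sample column."""
    p = len(z_col)
    # decreasing z, ties by ascending gene index
    order = sorted(range(p), key=lambda i: (-z_col[i], i))
    k = int(member.sum())
    weights = [abs(p / 2.0 - (pos + 1)) ** tau for pos in range(p)]
    member_weight_sum = sum(w for pos, w in enumerate(weights) if member[order[pos]])
    best_max, best_min, nu = 0.0, 0.0, 0.0
    for pos in range(p):
        gene = order[pos]
        if member[gene]:
            if member_weight_sum > 0:
                nu += weights[pos] / member_weight_sum
            else:
                nu += 1.0 / k
        else:
            nu -= 1.0 / (p - k)
        best_max = max(best_max, nu)
        best_min = min(best_min, nu)
    return max(0.0, best_max) + min(0.0, best_min)


def brute_u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x versus y by direct pair counting."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def exact_ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p-value by enumerating all group assignments.

    Assumes no ties across the pooled sample (the exact null distribution is
    then assignment-symmetric).
    """
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    observed = brute_u_statistic(x, y)
    total = 0
    as_extreme = 0
    center = n * m / 2.0
    for idx in itertools.combinations(range(n + m), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = brute_u_statistic(xs, ys)
        total += 1
        if abs(u - center) >= abs(observed - center) - 1e-12:
            as_extreme += 1
    return as_extreme / total


def brute_harrell_c(times, events, risks) -> float:
    """Harrell concordance by exhaustive pair enumeration."""
    num, den = 0.0, 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1.0
                if risks[i] > risks[j]:
                    num += 1.0
                elif risks[i] == risks[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def brute_fisher_upper(N: int, K: int, n: int, k: int) -> float:
    """One-sided (upper) Fisher exact p by direct hypergeometric summation."""
    p = 0.0
    for kk in range(k, min(K, n) + 1):
        p += comb(K, kk) * comb(N - K, n - kk) / comb(N, n)
    return p


def brute_roc_auc(scores, labels) -> float:
    """AUC by pairwise comparison of all positive/negative score pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = len(pos) * len(neg)
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / total
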