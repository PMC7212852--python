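"""Independent brute-force reference implementations used as test oracles.

Each oracle takes a different code path from the package: the Welch oracle
is scipy's t-test (the package computes the closed form itself), the BH
oracle is an explicit step-up loop (the package delegates to statsmodels),
the hypergeometric oracle enumerates the tail with exact integer
combinatorics (the package uses scipy's survival function), and the Ward
oracle agglomerates via the Lance-Williams recurrence (the package uses
scipy's linkage).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def welch_oracle(a, b) -> tuple[float, float, float]:
    """Welch t, df, two-sided p via scipy."""
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Hand-written Benjamini-Hochberg step-up with monotonicity."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def hypergeom_tail_oracle(k: int, M: int, n: int, N: int) -> float:
    """Exact tail enumeration: P(X >= k), X ~ Hypergeom(M, n, N)."""
    total = 0
    for x in range(k, min(n, N) + 1):
        total += math.comb(n, x) * math.comb(M - n, N - x)
    return total / math.comb(M, N)


def ward_linkage_oracle(X: np.ndarray) -> np.ndarray:
    """Brute-force Ward-D2 agglomeration via the Lance-Williams recurrence.

    Maintains the full inter-cluster distance matrix and merges the
    closest pair (lowest-index tie-break), updating squared distances with
    d(k, i∪j)^2 = ((n_k+n_i) d_ki^2 + (n_k+n_j) d_kj^2 - n_k d_ij^2)
    / (n_k+n_i+n_j).  Returns a scipy-style linkage matrix.
    """
    n = X.shape[0]
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(((X[i] - X[j]) ** 2).sum())

    def dist2(a, b):
        return d2[(min(a, b), max(a, b))]

    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai, a in enumerate(active):
            for b in active[ai + 1:]:
                key = (dist2(a, b), a, b)
                if best is None or key < best:
                    best = key
        dd, a, b = best
        merges.append((a, b, math.sqrt(dd), sizes[a] + sizes[b]))
        for k in active:
            if k in (a, b):
                continue
            nk, na, nb = sizes[k], sizes[a], sizes[b]
            d2[(min(k, next_id), max(k, next_id))] = (
                (nk + na) * dist2(k, a) + (nk + nb) * dist2(k, b) - nk * dd
            ) / (nk + na + nb)
        sizes[next_id] = sizes[a] + sizes[b]
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return np.array([[a, b, h, s] for a, b, h, s in merges])
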