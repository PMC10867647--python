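"""Independent reference implementations used as oracles in tests.

These deliberately use explicit Python loops and textbook formulas, coded
separately from the package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def reference_memberships(x: np.ndarray, v: np.ndarray, m: float) -> np.ndarray:
    """Naive fuzzy membership update: u_ik = [sum_j (d_ik/d_ij)^(2/(m-1))]^-1."""
    n, c = x.shape[0], v.shape[0]
    u = np.zeros((n, c))
    for i in range(n):
        d = [math.dist(x[i], v[k]) for k in range(c)]
        zeros = [k for k in range(c) if d[k] == 0.0]
        if zeros:
            for k in zeros:
                u[i, k] = 1.0 / len(zeros)
            continue
        for k in range(c):
            u[i, k] = 1.0 / sum((d[k] / d[j]) ** (2.0 / (m - 1.0)) for j in range(c))
    return u


def reference_fcm(x: np.ndarray, v0: np.ndarray, m: float, sweeps: int):
    """Naive alternating-update fuzzy c-means from given initial centroids.

    Mirrors the update order (memberships from centroids first, then
    `sweeps` centroid/membership sweeps) so a run with tol=0 and
    max_iter=sweeps is directly comparable. Returns (u, v, objective).
    """
    v = np.array(v0, dtype=float, copy=True)
    c = v.shape[0]
    u = reference_memberships(x, v, m)
    for _ in range(sweeps):
        for k in range(c):
            num = np.zeros(x.shape[1])
            den = 0.0
            for i in range(x.shape[0]):
                w = u[i, k] ** m
                num += w * x[i]
                den += w
            v[k] = num / den
        u = reference_memberships(x, v, m)
    objective = 0.0
    for i in range(x.shape[0]):
        for k in range(c):
            objective += u[i, k] ** m * math.dist(x[i], v[k]) ** 2
    return u, v, objective


def hypergeom_tail_comb(k: int, n_universe: int, n_pathway: int, n_selected: int) -> float:
    """P[X >= k] by direct combinatorial summation."""
    total = math.comb(n_universe, n_selected)
    acc = 0
    for j in range(k, min(n_pathway, n_selected) + 1):
        acc += math.comb(n_pathway, j) * math.comb(n_universe - n_pathway, n_selected - j)
    return acc / total


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, coded by hand."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q
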