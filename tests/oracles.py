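"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (plain loops, direct formulas) kept
separate from the library code paths they validate.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def exact_permutation_p(group1, group2) -> float:
    """Enumerate every reassignment of the pooled values to the two group
    sizes and count |mean difference| at least as extreme as observed."""
    x = list(map(float, group1))
    y = list(map(float, group2))
    pooled = x + y
    n1 = len(x)
    observed = abs(sum(x) / n1 - sum(y) / len(y))
    hits = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        stat = abs(sum(g1) / len(g1) - sum(g2) / len(g2))
        if stat >= observed - 1e-12:
            hits += 1
    return hits / total


def bhy_stepup(p_values) -> np.ndarray:
    """Direct Benjamini-Yekutieli step-up: p_adj(i) = min_{j>=i} min(1,
    p(j) * m * c(m) / j) on sorted p, restored to input order."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p)
    adj_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        val = min(1.0, p[order[i]] * m * c_m / (i + 1))
        running = min(running, val)
        adj_sorted[i] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def renyi_total_entropy(histogram, t: int, alpha: float) -> float:
    """Total Rényi entropy of the split at threshold t, computed naively."""
    hist = np.asarray(histogram, dtype=float)
    p = hist / hist.sum()
    p1 = p[: t + 1].sum()
    p2 = p[t + 1:].sum()
    if p1 <= 0 or p2 <= 0:
        return -np.inf
    back = [pi / p1 for pi in p[: t + 1] if pi > 0]
    fore = [pi / p2 for pi in p[t + 1:] if pi > 0]
    if abs(alpha - 1.0) < 1e-12:
        return (-sum(b * np.log(b) for b in back)
                - sum(f * np.log(f) for f in fore))
    sb = sum(b**alpha for b in back)
    sf = sum(f**alpha for f in fore)
    return float(np.log(sb * sf) / (1.0 - alpha))


def _lw_update(method, d_ik, d_jk, d_ij, ni, nj, nk):
    if method == "average":
        return (ni * d_ik + nj * d_jk) / (ni + nj)
    if method == "ward":
        n = ni + nj + nk
        return np.sqrt(((ni + nk) * d_ik**2 + (nj + nk) * d_jk**2
                        - nk * d_ij**2) / n)
    raise ValueError(method)


def brute_force_linkage(X_or_D, method: str, metric: str = "euclidean") -> np.ndarray:
    """O(n^3) agglomerative clustering via the Lance-Williams recurrence.

    Returns a linkage matrix comparable with scipy's (cluster ids assigned in
    merge order; rows sorted by height are compared on heights only).
    """
    X = np.asarray(X_or_D, dtype=float)
    n = X.shape[0]
    if metric == "euclidean":
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    elif metric == "correlation":
        Xc = X - X.mean(axis=1, keepdims=True)
        norm = np.sqrt((Xc**2).sum(axis=1))
        D = 1.0 - (Xc @ Xc.T) / np.outer(norm, norm)
        np.fill_diagonal(D, 0.0)
    else:
        raise ValueError(metric)

    active = {i: (i, 1) for i in range(n)}   # slot -> (cluster id, size)
    dist = {(min(a, b), max(a, b)): D[a, b]
            for a in range(n) for b in range(a + 1, n)}
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        (i, j), d_ij = min(dist.items(), key=lambda kv: kv[1])
        id_i, n_i = active[i]
        id_j, n_j = active[j]
        Z[step] = [min(id_i, id_j), max(id_i, id_j), d_ij, n_i + n_j]
        for k in list(active):
            if k in (i, j):
                continue
            d_ik = dist[(min(i, k), max(i, k))]
            d_jk = dist[(min(j, k), max(j, k))]
            nk = active[k][1]
            new = _lw_update(method, d_ik, d_jk, d_ij, n_i, n_j, nk)
            dist[(min(i, k), max(i, k))] = new
        for k in list(dist):
            if j in k:
                del dist[k]
        del active[j]
        active[i] = (next_id, n_i + n_j)
        next_id += 1
    return Z
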