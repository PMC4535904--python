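"""Brute-force reference implementations used only as test oracles.

Everything here is deliberately naive (exhaustive enumeration, direct
textbook formulas) and independent of the package's code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def exhaustive_kmeans_inertia(X: np.ndarray, k: int) -> float:
    """Global minimum of the k-means objective over all label assignments."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    best = math.inf
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) != k:
            continue
        labels = np.asarray(labels)
        inertia = 0.0
        for c in range(k):
            pts = X[labels == c]
            inertia += float(((pts - pts.mean(axis=0)) ** 2).sum())
        best = min(best, inertia)
    return best


def silhouette_direct(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Textbook a(i)/b(i) silhouette with Euclidean distances."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    out = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if not same.any():
            out[i] = 0.0
            continue
        a = D[i, same].mean()
        b = min(
            D[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        out[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return out


def naive_linkage(X: np.ndarray, method: str) -> np.ndarray:
    """O(n^3) agglomeration returning a scipy-style linkage matrix."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            A, B = X[clusters[a]], X[clusters[b]]
            if method == "ward":
                d = math.sqrt(2 * len(A) * len(B) / (len(A) + len(B))) * float(
                    np.linalg.norm(A.mean(0) - B.mean(0))
                )
            elif method == "single":
                d = float(
                    min(
                        np.linalg.norm(x - y)
                        for x in A
                        for y in B
                    )
                )
            else:
                raise ValueError(method)
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append([a, b, d, len(clusters[a]) + len(clusters[b])])
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.asarray(merges)


def binomial_tail_ge(c: int, n: int, p: float) -> float:
    """Exact P(X >= c) for X ~ Binomial(n, p) via integer binomials."""
    return float(
        sum(math.comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(c, n + 1))
    )


def critical_count_direct(n: int, p: float = 0.5, alpha: float = 0.05):
    for c in range(n + 1):
        if binomial_tail_ge(c, n, p) <= alpha:
            return c
    return None


def _ranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (midranks for ties), 1-based."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def kruskal_wallis_direct(groups) -> float:
    """Tie-corrected H from the textbook rank formula."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = _ranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


def friedman_direct(table: np.ndarray) -> float:
    """Friedman chi-square from within-block average ranks (no tie term)."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    ranks = np.vstack([_ranks(row) for row in table])
    col_sums = ranks.sum(axis=0)
    return float(12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3 * n * (k + 1))


def mann_whitney_enumeration(x, y):
    """U of the first sample plus the exact null mean/SD of U from full
    enumeration of group assignments over the pooled values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    nx = len(x)
    ranks = _ranks(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), nx):
        r = ranks[list(idx)]
        us.append(r.sum() - nx * (nx + 1) / 2)
    us = np.asarray(us)
    return float(u_obs), float(us.mean()), float(us.std(ddof=0))


def holm_decisions_direct(p_values, alpha):
    """Step-down Holm by hand: sort, compare p_(i) to alpha/(m-i), stop at
    the first failure."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank_i, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank_i):
            reject[idx] = True
        else:
            break
    return reject
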