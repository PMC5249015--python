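"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# brute-force DTW oracle (exhaustive path enumeration)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def all_warping_paths(n: int, m: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    """Every monotone path from (0, 0) to (n-1, m-1) with steps in
    {(1,0),(0,1),(1,1)}, built recursively."""
    if n == 1 and m == 1:
        return (((0, 0),),)
    out = []
    if n > 1 and m > 1:
        for p in all_warping_paths(n - 1, m - 1):
            out.append(p + ((n - 1, m - 1),))
    if n > 1:
        for p in all_warping_paths(n - 1, m):
            out.append(p + ((n - 1, m - 1),))
    if m > 1:
        for p in all_warping_paths(n, m - 1):
            out.append(p + ((n - 1, m - 1),))
    return tuple(out)


def local_dist(x: np.ndarray, y: np.ndarray, metric: str) -> float:
    if metric == "sqeuclidean":
        return float(((x - y) ** 2).sum())
    # cosine with the zero-vector convention d(x,0)=1, d(0,0)=0
    nx = float(np.sqrt((x * x).sum()))
    ny = float(np.sqrt((y * y).sum()))
    if nx == 0.0 and ny == 0.0:
        return 0.0
    if nx == 0.0 or ny == 0.0:
        return 1.0
    return max(0.0, 1.0 - float((x * y).sum()) / (nx * ny))


def in_band(i: int, j: int, n: int, m: int, band: int) -> bool:
    """Mirror of the implementation's band rule on 1-based DP coordinates."""
    if band <= 0:
        return True
    w = max(band, abs(n - m) + 1)
    c = i * m / n
    return math.ceil(c - w) <= j <= math.floor(c + w)


def brute_dtw(
    a: np.ndarray,
    b: np.ndarray,
    metric: str = "sqeuclidean",
    band: int = 0,
    gamma: float = 1.0,
    run_cap: int = 8,
) -> float:
    """Minimum path cost by exhaustive enumeration.

    Non-diagonal steps compound: the k-th consecutive non-diagonal step
    multiplies its local cost by gamma**min(k, run_cap); a diagonal step
    resets the run.  gamma=1 gives the plain unweighted sum.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(b, dtype=float).T).T
    n, m = a.shape[0], b.shape[0]
    d = np.array([[local_dist(a[i], b[j], metric) for j in range(m)] for i in range(n)])
    best = np.inf
    for path in all_warping_paths(n, m):
        if band > 0 and not all(in_band(i + 1, j + 1, n, m, band) for i, j in path):
            continue
        cost = d[path[0]]
        run = 0
        for (pi, pj), (ci, cj) in zip(path, path[1:]):
            if ci == pi + 1 and cj == pj + 1:
                run = 0
            else:
                run += 1
            cost += d[ci, cj] * gamma ** min(run, run_cap)
        if cost < best:
            best = cost
    return float(best)


# ---------------------------------------------------------------------------
# brute-force complete-linkage oracle
# ---------------------------------------------------------------------------


def brute_complete_linkage_labels(square: np.ndarray, n_clusters: int) -> list[set[int]]:
    """Agglomerative complete linkage by direct definition.

    Returns the partition (list of index sets) after merging down to
    ``n_clusters`` groups; each merge joins the pair of clusters whose
    *maximum* cross distance is smallest.
    """
    clusters: list[set[int]] = [{i} for i in range(square.shape[0])]
    while len(clusters) > n_clusters:
        best = None
        best_d = np.inf
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = max(square[i, j] for i in clusters[x] for j in clusters[y])
                if d < best_d:
                    best_d = d
                    best = (x, y)
        x, y = best
        clusters[x] |= clusters[y]
        del clusters[y]
    return clusters


def same_partition(labels_a, labels_b) -> bool:
    """True when two labelings induce the same partition of the items."""
    groups_a = {}
    groups_b = {}
    for k, (la, lb) in enumerate(zip(labels_a, labels_b)):
        groups_a.setdefault(la, set()).add(k)
        groups_b.setdefault(lb, set()).add(k)
    return set(map(frozenset, groups_a.values())) == set(map(frozenset, groups_b.values()))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
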