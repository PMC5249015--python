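"""Pairwise warping distances, complete-linkage dendrograms, and prototypes.

Shape clustering proceeds in two stages: all pairwise flip-aware DTW
distances are computed once (the O(N_peaks^2) step), then agglomerative
hierarchical clustering with complete linkage is run on the condensed
matrix.  Complete linkage scores a merge by the *largest* pairwise distance
between the two groups, which avoids the chaining artefacts single linkage
produces on elongated shape families.

Every node of the resulting dendrogram carries a *prototype*: a sequence
representative of the leaves below it, built by weighted DTW averaging of
its two children's prototypes (prioritised shape averaging with a length
rescaling step, see :func:`average_profiles`).
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .dtw import (
    DtwConfig,
    _as_values,
    _gamma_powers,
    _normalize_heights,
    _pairwise_flip_aware,
    _resolve_metric,
    flip_aware_distance,
)
from .profiles import Profile, ProfileSet

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "Prototype",
    "pairwise_distances",
    "build_dendrogram",
    "average_profiles",
    "warp_onto_prototype",
]


@dataclass
class DistanceMatrix:
    """Condensed pairwise flip-aware DTW distances plus per-pair flip flags."""

    condensed: np.ndarray
    flips: np.ndarray
    names: list[str]

    @property
    def n(self) -> int:
        return len(self.names)

    def square(self) -> np.ndarray:
        return squareform(self.condensed)

    def pair_index(self, i: int, j: int) -> int:
        if i == j:
            raise ValueError("condensed form has no diagonal entries")
        if i > j:
            i, j = j, i
        return self.n * i - i * (i + 1) // 2 + (j - i - 1)

    def __getitem__(self, ij: tuple[int, int]) -> float:
        i, j = ij
        if i == j:
            return 0.0
        return float(self.condensed[self.pair_index(i, j)])

    def to_tsv(self, path: str | Path, square: bool = False) -> None:
        path = Path(path)
        with path.open("w") as fh:
            if square:
                sq = self.square()
                fh.write("name\t" + "\t".join(self.names) + "\n")
                for name, row in zip(self.names, sq):
                    fh.write(name + "\t" + "\t".join(format(v, "g") for v in row) + "\n")
            else:
                fh.write("name_a\tname_b\tdistance\tflipped\n")
                idx = 0
                for i in range(self.n):
                    for j in range(i + 1, self.n):
                        fh.write(
                            f"{self.names[i]}\t{self.names[j]}\t"
                            f"{self.condensed[idx]:g}\t{int(self.flips[idx])}\n"
                        )
                        idx += 1


def _pack_profiles(
    profiles: ProfileSet | Sequence, config: DtwConfig
) -> tuple[np.ndarray, np.ndarray, int, DtwConfig]:
    """Zero-pad profiles into one (n, max_len, tracks) array for the kernel."""
    arrays = [_as_values(p) for p in profiles]
    n_tracks = arrays[0].shape[1]
    for a in arrays:
        if a.shape[1] != n_tracks:
            raise ValueError("profiles differ in track count")
    metric_code, config = _resolve_metric(config, n_tracks)
    if config.normalize_heights:
        arrays = [_normalize_heights(a) for a in arrays]
    lengths = np.array([a.shape[0] for a in arrays], dtype=np.int64)
    data = np.zeros((len(arrays), int(lengths.max()), n_tracks), dtype=np.float64)
    for k, a in enumerate(arrays):
        data[k, : a.shape[0], :] = a
    return data, lengths, metric_code, config


def pairwise_distances(
    profiles: ProfileSet,
    config: DtwConfig | None = None,
    workers: int = 1,
) -> DistanceMatrix:
    """All N(N-1)/2 flip-aware DTW distances between the given profiles.

    Each pair is an independent computation, so the result is identical for
    any worker count and any evaluation order; workers > 1 splits the rows
    across threads (the DP kernel releases the GIL).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    config = config or DtwConfig()
    data, lengths, metric_code, config = _pack_profiles(profiles, config)
    names = [getattr(p, "name", f"profile_{k}") for k, p in enumerate(profiles)]
    n = len(lengths)
    gpow = _gamma_powers(config.stretch_penalty)
    if workers <= 1:
        condensed, flips = _pairwise_flip_aware(
            data, lengths, metric_code, config.band_width, gpow, config.flip_aware
        )
        return DistanceMatrix(condensed, flips, names)
    condensed = np.empty(n * (n - 1) // 2)
    flips = np.zeros(n * (n - 1) // 2, dtype=bool)
    bounds = np.linspace(0, n, workers + 1).astype(int)

    def run_rows(i0: int, i1: int):
        sub_d, sub_f = _pairwise_flip_aware_rows(
            data, lengths, metric_code, config.band_width, gpow,
            config.flip_aware, i0, i1,
        )
        return i0, i1, sub_d, sub_f

    with ThreadPoolExecutor(max_workers=workers) as pool:
        for i0, i1, sub_d, sub_f in pool.map(lambda b: run_rows(*b), zip(bounds[:-1], bounds[1:])):
            off = 0
            for i in range(i0, i1):
                start = n * i - i * (i + 1) // 2
                width = n - i - 1
                condensed[start : start + width] = sub_d[off : off + width]
                flips[start : start + width] = sub_f[off : off + width]
                off += width
    return DistanceMatrix(condensed, flips, names)


def _pairwise_flip_aware_rows(data, lengths, metric, band, gpow, flip_aware, i0, i1):
    """Row-block variant used by the threaded path; same per-pair arithmetic."""
    from .dtw import _pair_distance

    n = lengths.shape[0]
    total = sum(n - i - 1 for i in range(i0, i1))
    out = np.empty(total)
    flips = np.zeros(total, dtype=bool)
    idx = 0
    for i in range(i0, i1):
        a = data[i, : lengths[i], :]
        for j in range(i + 1, n):
            b = data[j, : lengths[j], :]
            d_fwd = _pair_distance(a, b, metric, band, gpow)
            if flip_aware:
                d_rev = _pair_distance(a, b[::-1, :].copy(), metric, band, gpow)
                if d_rev < d_fwd:
                    out[idx] = d_rev
                    flips[idx] = True
                else:
                    out[idx] = d_fwd
            else:
                out[idx] = d_fwd
            idx += 1
    return out, flips


# ---------------------------------------------------------------------------
# prototypes
# ---------------------------------------------------------------------------


@dataclass
class Prototype:
    """Representative sequence for a dendrogram node.

    ``weight`` counts the leaves it summarizes; a leaf's prototype is the
    leaf's own profile with weight 1.
    """

    values: np.ndarray
    weight: int

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def n_tracks(self) -> int:
        return self.values.shape[1]


def _resample(values: np.ndarray, new_len: int) -> np.ndarray:
    """Linear resampling of each track to ``new_len`` bins."""
    old_len = values.shape[0]
    if old_len == new_len:
        return values
    if old_len == 1:
        return np.repeat(values, new_len, axis=0)
    x_new = np.linspace(0.0, old_len - 1.0, new_len)
    x_old = np.arange(old_len, dtype=np.float64)
    return np.column_stack([np.interp(x_new, x_old, values[:, t]) for t in range(values.shape[1])])


def average_profiles(
    heavy: Prototype, light: Prototype, config: DtwConfig | None = None
) -> Prototype:
    """Weighted DTW average of two prototypes (prioritised shape averaging).

    The heavier prototype keeps its orientation; the lighter one adopts the
    orientation minimizing the DTW distance.  Along the optimal path the
    value at each step is the leaf-weighted mean of the matched bins; steps
    sharing the same heavy-side bin are mean-pooled, and the result is then
    linearly rescaled to the leaf-weighted mean of the two lengths so that
    repeated averaging does not drift toward either child's length.
    """
    config = config or DtwConfig()
    if light.weight > heavy.weight:
        heavy, light = light, heavy
    res = flip_aware_distance(heavy.values, light.values, config)
    light_vals = light.values[::-1] if res.flipped else light.values
    w1, w2 = float(heavy.weight), float(light.weight)
    pairs = res.path.pairs
    step_vals = (w1 * heavy.values[pairs[:, 0]] + w2 * light_vals[pairs[:, 1]]) / (w1 + w2)
    # mean-pool steps that map to the same heavy-side bin
    pooled = np.zeros((heavy.length, heavy.n_tracks))
    counts = np.zeros(heavy.length)
    np.add.at(pooled, pairs[:, 0], step_vals)
    np.add.at(counts, pairs[:, 0], 1.0)
    pooled /= counts[:, None]
    target_len = int(round((w1 * heavy.length + w2 * light.length) / (w1 + w2)))
    return Prototype(_resample(pooled, max(1, target_len)), heavy.weight + light.weight)


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over a profile set.

    ``merges`` is the standard linkage matrix: row i merges nodes
    ``merges[i, 0]`` and ``merges[i, 1]`` (ids < n are leaves, id n + i is
    the node created by row i) at height ``merges[i, 2]`` into a node with
    ``merges[i, 3]`` leaves.  Prototypes are computed lazily per node.
    """

    merges: np.ndarray
    profiles: ProfileSet
    config: DtwConfig

    def __post_init__(self):
        self._prototypes: dict[int, Prototype] = {}

    @property
    def n_leaves(self) -> int:
        return self.merges.shape[0] + 1

    @property
    def n_nodes(self) -> int:
        """Internal nodes only: N_peaks - 1."""
        return self.merges.shape[0]

    def cut(self, n_clusters: int | None = None, height: float | None = None) -> np.ndarray:
        """Cluster labels (0-based, ordered as the input profiles).

        Exactly one of ``n_clusters`` and ``height`` must be given; the
        ``n_clusters`` form always yields that many non-empty groups.
        """
        if (n_clusters is None) == (height is None):
            raise ValueError("give exactly one of n_clusters or height")
        if n_clusters is not None:
            if not 1 <= n_clusters <= self.n_leaves:
                raise ValueError(f"n_clusters must be in [1, {self.n_leaves}]")
            return cut_tree(self.merges, n_clusters=n_clusters).ravel()
        return cut_tree(self.merges, height=height).ravel()

    def prototype(self, node_id: int) -> Prototype:
        """Prototype of any node; leaves are their own profiles (weight 1)."""
        n = self.n_leaves
        cache = self._prototypes
        stack = [node_id]
        while stack:
            nid = stack[-1]
            if nid in cache:
                stack.pop()
                continue
            if nid < n:
                cache[nid] = Prototype(_as_values(self.profiles[nid]).copy(), 1)
                stack.pop()
                continue
            row = self.merges[nid - n]
            a, b = int(row[0]), int(row[1])
            pending = [c for c in (a, b) if c not in cache]
            if pending:
                stack.extend(pending)
            else:
                cache[nid] = average_profiles(cache[a], cache[b], self.config)
                stack.pop()
        return cache[node_id]

    def cluster_prototypes(self, labels: np.ndarray) -> dict[int, Prototype]:
        """Prototype of the dendrogram node spanning each cluster.

        For a cut produced by :meth:`cut` each cluster corresponds to one
        subtree; its prototype is that subtree's node prototype.
        """
        n = self.n_leaves
        # map each node to the set of leaf labels below it, bottom-up
        label_of_node: dict[int, int] = {}
        out: dict[int, Prototype] = {}
        members: dict[int, set[int]] = {i: {int(labels[i])} for i in range(n)}
        for i in range(n):
            label_of_node[i] = int(labels[i])
        for k, row in enumerate(self.merges):
            a, b = int(row[0]), int(row[1])
            members[n + k] = members[a] | members[b]
        for lab in sorted(set(int(l) for l in labels)):
            # the cluster's node: the largest node whose leaves all share lab
            best = None
            for node_id in range(n + self.n_nodes):
                if members[node_id] == {lab}:
                    best = node_id
            out[lab] = self.prototype(best)
        return out

    def to_linkage_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("node_id\tchild_a\tchild_b\theight\tn_leaves\n")
            n = self.n_leaves
            for k, row in enumerate(self.merges):
                fh.write(
                    f"{n + k}\t{int(row[0])}\t{int(row[1])}\t{row[2]:g}\t{int(row[3])}\n"
                )

    def to_newick(self) -> str:
        """Newick string with leaf names and internal node ids, branch
        lengths taken as merge-height differences."""
        n = self.n_leaves
        heights = np.concatenate([np.zeros(n), self.merges[:, 2]])
        names = self.profiles.names if self.profiles is not None else [str(i) for i in range(n)]
        parts: dict[int, str] = {}
        for i in range(n):
            parts[i] = names[i]
        for k, row in enumerate(self.merges):
            a, b = int(row[0]), int(row[1])
            node = n + k
            bl_a = heights[node] - heights[a]
            bl_b = heights[node] - heights[b]
            parts[node] = f"({parts[a]}:{bl_a:g},{parts[b]}:{bl_b:g})node_{node}"
            del parts[a], parts[b]
        root = n + self.n_nodes - 1
        return parts[root] + ";"


def build_dendrogram(
    dm: DistanceMatrix, profiles: ProfileSet | None = None, config: DtwConfig | None = None
) -> Dendrogram:
    """Complete-linkage agglomerative clustering of a distance matrix.

    The dendrogram has exactly N_peaks - 1 internal nodes, each a candidate
    clustering.  Merge heights are monotone non-decreasing (a property of
    complete linkage).
    """
    if not np.isfinite(dm.condensed).all():
        raise ValueError("distance matrix contains non-finite entries")
    merges = linkage(dm.condensed, method="complete")
    return Dendrogram(merges, profiles, config or DtwConfig())


def warp_onto_prototype(profile, prototype: Prototype, config: DtwConfig | None = None) -> np.ndarray:
    """Warp a profile onto a prototype's time axis.

    The profile is aligned to the prototype flip-aware; every prototype bin
    receives the mean of the profile bins mapped to it, giving a warped
    profile of exactly the prototype's length.
    """
    config = config or DtwConfig()
    res = flip_aware_distance(prototype.values, profile, config)
    vals = _as_values(profile)
    if config.normalize_heights:
        vals = _normalize_heights(vals)
    if res.flipped:
        vals = vals[::-1]
    pairs = res.path.pairs
    out = np.zeros((prototype.length, vals.shape[1]))
    counts = np.zeros(prototype.length)
    np.add.at(out, pairs[:, 0], vals[pairs[:, 1]])
    np.add.at(counts, pairs[:, 0], 1.0)
    return out / counts[:, None]
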