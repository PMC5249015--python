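"""Band-constrained, flip-aware dynamic time warping between binned coverage profiles.

The aligner operates on sequences of per-bin value vectors (one vector entry
per epigenomic track) and minimises the summed local distance over a warping
path subject to the classical constraints: endpoints pinned to each other,
both index sets non-decreasing, and a maximum step of one in each index.
Every bin of each sequence is therefore matched to at least one bin of the
other, so local stretches and compressions of the signal are absorbed by the
path rather than penalised as mismatches.

A Sakoe-Chiba band restricts the path to a corridor around the slanted
diagonal, bounding both the amount of compression and the run time
(O(k * max(N, M)) for half-width ``k``).  Because histone-mark profiles have
no preferred reading direction, the flip-aware distance evaluates both the
given orientation and the reversal of the second sequence and keeps the
smaller of the two distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "DtwConfig",
    "WarpingPath",
    "AlignmentResult",
    "local_distance",
    "dtw_align",
    "flip_aware_distance",
]

_METRICS = {"sqeuclidean": 0, "cosine": 1}


@dataclass(frozen=True)
class DtwConfig:
    """Settings for a DTW comparison.

    Parameters
    ----------
    metric:
        Local distance between bin vectors: ``"sqeuclidean"`` (default) or
        ``"cosine"``.  Cosine distance for single-track profiles degenerates
        to values in {0, 2}, so it falls back to squared Euclidean on
        height-normalized values (with a warning).
    band_width:
        Sakoe-Chiba half-width ``k`` in bins; 0 disables the band.  For
        sequences of unequal length the band follows the slanted diagonal
        ``j ~ i * M / N`` with effective half-width ``max(k, |N - M| + 1)``
        so that the corridor always admits a complete path.
    flip_aware:
        If true, pairwise comparisons also evaluate the reversed orientation
        of the second profile and keep the smaller distance.
    normalize_heights:
        Divide each track by its own maximum before aligning, removing
        enrichment-level differences so that only shape contributes.
    stretch_penalty:
        Base ``gamma`` (>= 1) of the exponential penalty on compressing or
        stretching runs: the k-th consecutive non-diagonal step multiplies
        its local cost by ``gamma**k`` (saturating at ``gamma**8``), so an
        isolated insertion stays cheap while a long slide of one profile
        across the other becomes prohibitively expensive.  The default 1.0
        leaves the plain unweighted sum.
    """

    metric: str = "sqeuclidean"
    band_width: int = 0
    flip_aware: bool = True
    normalize_heights: bool = False
    stretch_penalty: float = 1.0

    def __post_init__(self) -> None:
        if self.metric not in _METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; choose from {sorted(_METRICS)}")
        if self.band_width < 0:
            raise ValueError("band_width must be >= 0")
        if self.stretch_penalty < 1.0:
            raise ValueError("stretch_penalty must be >= 1")


class WarpingPath:
    """Monotone index mapping between two sequences.

    ``pairs`` is a (K, 2) integer array of 0-based indices (i, j): bin i of
    the first sequence is matched to bin j of the second.  The path starts at
    (0, 0), ends at (N-1, M-1), each index is non-decreasing with steps of at
    most one, and no step leaves both indices unchanged.
    """

    __slots__ = ("pairs",)

    def __init__(self, pairs: np.ndarray):
        self.pairs = np.asarray(pairs, dtype=np.int64)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise ValueError("pairs must be a (K, 2) array")

    def __len__(self) -> int:
        return self.pairs.shape[0]

    def __iter__(self):
        return iter(map(tuple, self.pairs))

    def __repr__(self) -> str:
        return f"WarpingPath(K={len(self)})"

    def targets_of(self, i: int) -> np.ndarray:
        """All indices of the second sequence matched to source index ``i``."""
        return self.pairs[self.pairs[:, 0] == i, 1]

    def validate(self, n: int, m: int) -> None:
        p = self.pairs
        if tuple(p[0]) != (0, 0) or tuple(p[-1]) != (n - 1, m - 1):
            raise ValueError("path endpoints are not pinned")
        steps = np.diff(p, axis=0)
        if steps.size and (steps.min() < 0 or steps.max() > 1 or (steps.sum(axis=1) == 0).any()):
            raise ValueError("path steps must be in {(0,1),(1,0),(1,1)}")


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal warping of one profile pair: path, total distance, orientation."""

    path: WarpingPath
    distance: float
    flipped: bool = False


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True, nogil=True, inline="always")
def _local(a, b, i, j, metric):
    if metric == 0:  # squared Euclidean
        s = 0.0
        for t in range(a.shape[1]):
            diff = a[i, t] - b[j, t]
            s += diff * diff
        return s
    # cosine: 1 - <x, y> / (|x| |y|); zero-vector convention d(x,0)=1, d(0,0)=0
    dot = 0.0
    na = 0.0
    nb = 0.0
    for t in range(a.shape[1]):
        dot += a[i, t] * b[j, t]
        na += a[i, t] * a[i, t]
        nb += b[j, t] * b[j, t]
    if na == 0.0 and nb == 0.0:
        return 0.0
    if na == 0.0 or nb == 0.0:
        return 1.0
    c = 1.0 - dot / math.sqrt(na * nb)
    return c if c > 0.0 else 0.0


@njit(cache=True, nogil=True, inline="always")
def _band_limits(i, n, m, band):
    """Inclusive (lo, hi) column range (1-based DP columns) for DP row i."""
    if band <= 0:
        return 1, m
    w = band
    slack = abs(n - m) + 1
    if slack > w:
        w = slack
    c = i * m / n
    lo = int(math.ceil(c - w))
    hi = int(math.floor(c + w))
    if lo < 1:
        lo = 1
    if hi > m:
        hi = m
    return lo, hi


@njit(cache=True, nogil=True)
def _accumulate(a, b, metric, band):
    """Full (N+1, M+1) accumulated-cost matrix; D[N, M] is the distance."""
    n = a.shape[0]
    m = b.shape[0]
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        lo, hi = _band_limits(i, n, m, band)
        for j in range(lo, hi + 1):
            d = _local(a, b, i - 1, j - 1, metric)
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = best + d
    return acc


@njit(cache=True, nogil=True)
def _distance_only(a, b, metric, band):
    """Rolling two-row DP returning only the total distance."""
    n = a.shape[0]
    m = b.shape[0]
    prev = np.full(m + 1, np.inf)
    cur = np.full(m + 1, np.inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        lo, hi = _band_limits(i, n, m, band)
        for j in range(0, lo):
            cur[j] = np.inf
        for j in range(hi + 1, m + 1):
            cur[j] = np.inf
        for j in range(lo, hi + 1):
            d = _local(a, b, i - 1, j - 1, metric)
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = best + d
        prev, cur = cur, prev
    return prev[m]


# Saturation of the exponential stretch penalty: the r-th consecutive
# non-diagonal step costs local * gamma**min(r, _RUN_CAP).
_RUN_CAP = 8


@njit(cache=True, nogil=True)
def _accumulate_runs(a, b, metric, band, gpow):
    """Layered accumulated-cost tensor for the run-compounded stretch penalty.

    ``acc[i, j, r]`` is the cheapest path to cell (i, j) whose trailing run
    of non-diagonal steps has length r (saturating at the last layer); a
    diagonal step resets the run.  The distance is ``min_r acc[N, M, r]``.
    """
    n = a.shape[0]
    m = b.shape[0]
    layers = gpow.shape[0]
    cap = layers - 1
    acc = np.full((n + 1, m + 1, layers), np.inf)
    acc[0, 0, 0] = 0.0
    for i in range(1, n + 1):
        lo, hi = _band_limits(i, n, m, band)
        for j in range(lo, hi + 1):
            d = _local(a, b, i - 1, j - 1, metric)
            # diagonal step: run resets, any predecessor layer allowed
            best = np.inf
            for r in range(layers):
                if acc[i - 1, j - 1, r] < best:
                    best = acc[i - 1, j - 1, r]
            acc[i, j, 0] = best + d
            # non-diagonal steps extend the run by one (saturating)
            for r in range(1, layers):
                best = acc[i - 1, j, r - 1]
                if acc[i, j - 1, r - 1] < best:
                    best = acc[i, j - 1, r - 1]
                if r == cap:
                    if acc[i - 1, j, cap] < best:
                        best = acc[i - 1, j, cap]
                    if acc[i, j - 1, cap] < best:
                        best = acc[i, j - 1, cap]
                acc[i, j, r] = best + d * gpow[r]
    return acc


@njit(cache=True, nogil=True)
def _distance_only_runs(a, b, metric, band, gpow):
    """Rolling two-row variant of :func:`_accumulate_runs`."""
    n = a.shape[0]
    m = b.shape[0]
    layers = gpow.shape[0]
    cap = layers - 1
    prev = np.full((m + 1, layers), np.inf)
    cur = np.full((m + 1, layers), np.inf)
    prev[0, 0] = 0.0
    for i in range(1, n + 1):
        lo, hi = _band_limits(i, n, m, band)
        for j in range(0, lo):
            for r in range(layers):
                cur[j, r] = np.inf
        for j in range(hi + 1, m + 1):
            for r in range(layers):
                cur[j, r] = np.inf
        for j in range(lo, hi + 1):
            d = _local(a, b, i - 1, j - 1, metric)
            best = np.inf
            for r in range(layers):
                if prev[j - 1, r] < best:
                    best = prev[j - 1, r]
            cur[j, 0] = best + d
            for r in range(1, layers):
                best = prev[j, r - 1]
                if cur[j - 1, r - 1] < best:
                    best = cur[j - 1, r - 1]
                if r == cap:
                    if prev[j, cap] < best:
                        best = prev[j, cap]
                    if cur[j - 1, cap] < best:
                        best = cur[j - 1, cap]
                cur[j, r] = best + d * gpow[r]
        tmp = prev
        prev = cur
        cur = tmp
    best = np.inf
    for r in range(layers):
        if prev[m, r] < best:
            best = prev[m, r]
    return best


@njit(cache=True, nogil=True, inline="always")
def _pair_distance(a, b, metric, band, gpow):
    if gpow.shape[0] == 1:  # gamma == 1: plain unweighted DP
        return _distance_only(a, b, metric, band)
    return _distance_only_runs(a, b, metric, band, gpow)


@njit(cache=True, nogil=True)
def _pairwise_flip_aware(data, lengths, metric, band, gpow, flip_aware):
    """Condensed flip-aware distances over ``data[k, :lengths[k], :]`` profiles."""
    n = lengths.shape[0]
    out = np.empty(n * (n - 1) // 2)
    flips = np.zeros(n * (n - 1) // 2, dtype=np.bool_)
    idx = 0
    for i in range(n):
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


def _gamma_powers(gamma: float) -> np.ndarray:
    """Penalty-factor table for the run-compounded stretch penalty.

    A single-entry table signals the plain (gamma == 1) recursion to the
    kernels; otherwise entry r holds gamma**min(r, _RUN_CAP).
    """
    if gamma == 1.0:
        return np.ones(1)
    return gamma ** np.minimum(np.arange(_RUN_CAP + 1), _RUN_CAP).astype(np.float64)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _as_values(profile) -> np.ndarray:
    """Accept a Profile-like object (``.values``) or a plain array.

    1-D input is treated as a single-track sequence.
    """
    values = getattr(profile, "values", profile)
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("profile values must be 1-D or (n_bins, n_tracks)")
    if arr.shape[0] == 0:
        raise ValueError("cannot align an empty profile")
    return np.ascontiguousarray(arr)


def _normalize_heights(arr: np.ndarray) -> np.ndarray:
    peaks = arr.max(axis=0)
    if (peaks <= 0).any():
        raise ValueError("cannot height-normalize a track whose maximum is 0")
    return arr / peaks


def _resolve_metric(config: DtwConfig, n_tracks: int) -> tuple[int, DtwConfig]:
    if config.metric == "cosine" and n_tracks == 1:
        warnings.warn(
            "cosine distance between scalars is degenerate; falling back to "
            "squared Euclidean on height-normalized values",
            stacklevel=3,
        )
        config = replace(config, metric="sqeuclidean", normalize_heights=True)
    return _METRICS[config.metric], config


def local_distance(x: Sequence[float] | float, y: Sequence[float] | float, metric: str = "sqeuclidean") -> float:
    """Local distance between two bin-value vectors (scalars allowed)."""
    xv = np.atleast_1d(np.asarray(x, dtype=np.float64))
    yv = np.atleast_1d(np.asarray(y, dtype=np.float64))
    if xv.shape != yv.shape:
        raise ValueError(f"dimensionality mismatch: {xv.shape} vs {yv.shape}")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    return float(_local(xv[None, :], yv[None, :], 0, 0, _METRICS[metric]))


def _backtrack(
    acc: np.ndarray,
    av: np.ndarray,
    bv: np.ndarray,
    metric_code: int,
    prefer_first: bool,
) -> np.ndarray:
    """Recover one optimal path from the accumulated-cost matrix.

    At each cell the local distance is recomputed and the predecessor whose
    DP sum reproduces ``acc[i, j]`` bit-exactly is chosen; ties prefer the
    diagonal step, then the step advancing the longer sequence
    (``prefer_first`` selects the first sequence), giving a deterministic,
    shortest-possible path.
    """
    n, m = acc.shape[0] - 1, acc.shape[1] - 1
    pairs = [(n - 1, m - 1)]
    i, j = n, m
    while i > 1 or j > 1:
        d = float(_local(av, bv, i - 1, j - 1, metric_code))
        moves = [((i - 1, j - 1), acc[i - 1, j - 1] + d)]
        vert = ((i - 1, j), acc[i - 1, j] + d)
        horiz = ((i, j - 1), acc[i, j - 1] + d)
        moves.extend([vert, horiz] if prefer_first else [horiz, vert])
        target = acc[i, j]
        step = None
        for pred, total in moves:
            if total == target:
                step = pred
                break
        if step is None:  # guard against pathological rounding; take the best
            step = min(moves, key=lambda t: t[1])[0]
        i, j = step
        pairs.append((i - 1, j - 1))
    pairs.reverse()
    return np.asarray(pairs, dtype=np.int64)


def _backtrack_runs(
    acc: np.ndarray,
    av: np.ndarray,
    bv: np.ndarray,
    metric_code: int,
    gpow: np.ndarray,
    prefer_first: bool,
) -> np.ndarray:
    """Backtrack through the layered (run-penalized) accumulated tensor.

    State is (cell, trailing-run layer).  Tie preferences mirror
    :func:`_backtrack`: diagonal first, then the step advancing the longer
    sequence; among layers the shortest run is preferred.
    """
    n, m = acc.shape[0] - 1, acc.shape[1] - 1
    cap = acc.shape[2] - 1
    r = int(np.argmin(acc[n, m]))  # argmin returns the lowest index on ties
    pairs = [(n - 1, m - 1)]
    i, j = n, m
    while i > 1 or j > 1:
        d = float(_local(av, bv, i - 1, j - 1, metric_code))
        target = acc[i, j, r]
        moves: list[tuple[tuple[int, int], int, float]] = []
        if r == 0:
            for rp in range(cap + 1):
                moves.append(((i - 1, j - 1), rp, acc[i - 1, j - 1, rp] + d))
        else:
            cost = d * gpow[r]
            vert = [((i - 1, j), r - 1, acc[i - 1, j, r - 1] + cost)]
            horiz = [((i, j - 1), r - 1, acc[i, j - 1, r - 1] + cost)]
            if r == cap:
                vert.append(((i - 1, j), cap, acc[i - 1, j, cap] + cost))
                horiz.append(((i, j - 1), cap, acc[i, j - 1, cap] + cost))
            moves.extend(vert + horiz if prefer_first else horiz + vert)
        step = None
        for pred, rp, total in moves:
            if total == target:
                step = (pred, rp)
                break
        if step is None:  # guard against pathological rounding; take the best
            best = min(moves, key=lambda t: t[2])
            step = (best[0], best[1])
        (i, j), r = step
        pairs.append((i - 1, j - 1))
    pairs.reverse()
    return np.asarray(pairs, dtype=np.int64)


def dtw_align(a, b, config: DtwConfig | None = None) -> AlignmentResult:
    """Optimal warping between two profiles in their given orientation.

    Returns the minimizing path and the raw (unnormalized) sum of local
    distances along it.  Complexity is O(band_width * max(N, M)) when the
    Sakoe-Chiba band is active, O(N * M) otherwise.
    """
    config = config or DtwConfig()
    av = _as_values(a)
    bv = _as_values(b)
    if av.shape[1] != bv.shape[1]:
        raise ValueError(f"track-count mismatch: {av.shape[1]} vs {bv.shape[1]}")
    metric_code, config = _resolve_metric(config, av.shape[1])
    if config.normalize_heights:
        av = _normalize_heights(av)
        bv = _normalize_heights(bv)
    gpow = _gamma_powers(config.stretch_penalty)
    prefer_first = av.shape[0] >= bv.shape[0]
    if gpow.shape[0] == 1:
        acc = _accumulate(av, bv, metric_code, config.band_width)
        distance = float(acc[av.shape[0], bv.shape[0]])
    else:
        acc = _accumulate_runs(av, bv, metric_code, config.band_width, gpow)
        distance = float(acc[av.shape[0], bv.shape[0]].min())
    if not np.isfinite(distance):
        raise RuntimeError("infeasible band: no admissible warping path")
    if gpow.shape[0] == 1:
        pairs = _backtrack(acc, av, bv, metric_code, prefer_first)
    else:
        pairs = _backtrack_runs(acc, av, bv, metric_code, gpow, prefer_first)
    path = WarpingPath(pairs)
    path.validate(av.shape[0], bv.shape[0])
    return AlignmentResult(path=path, distance=distance, flipped=False)


def flip_aware_distance(a, b, config: DtwConfig | None = None) -> AlignmentResult:
    """Smaller of the two DTW alignments: ``b`` as given versus ``b`` reversed.

    Reversal flips the bin order jointly across all tracks.  On an exact tie
    the unflipped orientation is reported, biasing toward the annotation
    strand.
    """
    config = config or DtwConfig()
    fwd = dtw_align(a, b, config)
    if not config.flip_aware:
        return fwd
    bv = _as_values(b)[::-1]
    rev = dtw_align(a, bv, config)
    if rev.distance < fwd.distance:
        return AlignmentResult(path=rev.path, distance=rev.distance, flipped=True)
    return fwd


def accumulated_cost_matrix(a, b, config: DtwConfig | None = None) -> np.ndarray:
    """Accumulated-cost matrix (without the padding row/column), for debugging
    and for distance-density plots of a single alignment."""
    config = config or DtwConfig()
    av = _as_values(a)
    bv = _as_values(b)
    metric_code, config = _resolve_metric(config, av.shape[1])
    if config.normalize_heights:
        av = _normalize_heights(av)
        bv = _normalize_heights(bv)
    gpow = _gamma_powers(config.stretch_penalty)
    if gpow.shape[0] == 1:
        return _accumulate(av, bv, metric_code, config.band_width)[1:, 1:]
    acc = _accumulate_runs(av, bv, metric_code, config.band_width, gpow)
    return acc[1:, 1:].min(axis=2)  # cheapest path to each cell over run states
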