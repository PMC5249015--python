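"""Tests for the synthetic benchmark: seeds, corruption, scoring."""

import numpy as np
import pytest

from peakwarp.dtw import DtwConfig
from peakwarp.simulate import (
    BENCHMARK_DTW_CONFIG,
    N_SEED_BINS,
    LabelledProfileSet,
    SimulationParams,
    cluster_labels_baseline,
    cluster_labels_dgw,
    corrupt_profile,
    make_synthetic_seeds,
    mcc_multiclass,
    rk_statistic,
    run_benchmark_grid,
    simulate_dataset,
)
from peakwarp.clustering import pairwise_distances


# ---------------------------------------------------------------------------
# seed contracts
# ---------------------------------------------------------------------------


def local_maxima_above_half(values):
    v = np.asarray(values, dtype=float).ravel()
    half = v.max() / 2
    return [
        i
        for i in range(1, len(v) - 1)
        if v[i] >= v[i - 1] and v[i] > v[i + 1] and v[i] > half
    ]


def test_seed_cardinality_and_shape_classes():
    seeds = make_synthetic_seeds()
    assert seeds.size == 5
    n_modes = [len(local_maxima_above_half(p.values)) for p in seeds]
    assert n_modes == [2, 2, 2, 1, 1]  # three bimodal, two unimodal


def test_seed_amplitudes_and_counts():
    for p in make_synthetic_seeds():
        assert p.n_bins == N_SEED_BINS
        assert np.array_equal(p.values, np.round(p.values))  # integer counts
        assert 50 <= p.values.max() <= 300


def test_seeds_pairwise_separated_after_normalization():
    seeds = make_synthetic_seeds()
    dm = pairwise_distances(seeds, DtwConfig(normalize_heights=True, band_width=6))
    assert (dm.condensed > 0).all()


def test_seed_flip_distance_below_between_class():
    """A reversed seed stays far closer to its own seed than to any other."""
    seeds = make_synthetic_seeds()
    cfg = DtwConfig(normalize_heights=True, band_width=6, flip_aware=False)
    dm = pairwise_distances(seeds, cfg)
    from peakwarp.dtw import dtw_align

    for i, p in enumerate(seeds):
        flip_d = dtw_align(p.values, p.values[::-1], cfg).distance
        between = min(dm[i, j] for j in range(5) if j != i)
        assert flip_d < between


def test_seeds_deterministic():
    a = make_synthetic_seeds()
    b = make_synthetic_seeds(rng_seed=123)  # shapes do not depend on the seed
    for p, q in zip(a, b):
        assert np.array_equal(p.values, q.values)


# ---------------------------------------------------------------------------
# corruption process
# ---------------------------------------------------------------------------


def test_corruption_identity_at_zero():
    seed = make_synthetic_seeds()[0]
    rng = np.random.default_rng(5)
    prof, flip = corrupt_profile(seed, SimulationParams(v=0, p=0, fp=0), rng)
    assert not flip
    assert np.array_equal(prof.values, seed.values)  # bit-exact


def test_corruption_flip_only():
    seed = make_synthetic_seeds()[0]
    rng = np.random.default_rng(5)
    flips = []
    for _ in range(200):
        prof, flip = corrupt_profile(seed, SimulationParams(v=0, p=0, fp=1.0), rng)
        flips.append(flip)
        assert np.array_equal(prof.values, seed.values[::-1])
    assert all(flips)


def test_corruption_expected_length():
    """E[length] = N * (1 + p^2 / (2 (1 - p))) under the 50/50 indel split
    with re-entrant duplication."""
    seed = make_synthetic_seeds()[0]
    rng = np.random.default_rng(11)
    for p in (0.1, 0.25, 0.4):
        lengths = [
            corrupt_profile(seed, SimulationParams(v=0, p=p, fp=0), rng)[0].n_bins
            for _ in range(3000)
        ]
        expected = N_SEED_BINS * (1 + p * p / (2 * (1 - p)))
        assert np.mean(lengths) == pytest.approx(expected, rel=0.02)


def test_corruption_noise_is_per_bin():
    """Multiplicative noise draws one factor per bin, shared across tracks."""
    region_values = np.column_stack([np.full(50, 100.0), np.full(50, 200.0)])
    from peakwarp.profiles import Profile, Region

    seed = Profile(Region("c", 0, 2500, "s"), region_values, 50, ["a", "b"])
    rng = np.random.default_rng(3)
    prof, _ = corrupt_profile(seed, SimulationParams(v=0.25, p=0, fp=0), rng)
    factors = prof.values / seed.values
    assert np.allclose(factors[:, 0], factors[:, 1])  # same factor on both tracks
    assert np.std(factors[:, 0]) > 0.2  # and it truly varies bin to bin
    assert prof.values.min() >= 0


def test_corruption_bin_map_tracks_sources():
    seed = make_synthetic_seeds()[1]
    rng = np.random.default_rng(9)
    for _ in range(50):
        prof, flip, src = corrupt_profile(
            seed, SimulationParams(v=0.1, p=0.3, fp=0.5), rng, return_bin_map=True
        )
        assert src.shape[0] == prof.n_bins
        ordered = src[::-1] if flip else src
        assert np.all(np.diff(ordered) >= 0)  # monotone in the unflipped frame
        assert set(ordered).issubset(range(seed.n_bins))


def test_simulation_params_validation():
    with pytest.raises(ValueError):
        SimulationParams(v=-0.1)
    with pytest.raises(ValueError):
        SimulationParams(p=1.0)
    with pytest.raises(ValueError):
        SimulationParams(fp=1.5)


def test_dataset_composition_and_determinism():
    data = simulate_dataset(SimulationParams(v=0.1, p=0.1, fp=0.1), rng_seed=7)
    assert data.size == 500
    assert np.array_equal(np.bincount(data.labels)[1:], np.full(5, 100))
    again = simulate_dataset(SimulationParams(v=0.1, p=0.1, fp=0.1), rng_seed=7)
    for p, q in zip(data.profiles, again.profiles):
        assert np.array_equal(p.values, q.values)
    other = simulate_dataset(SimulationParams(v=0.1, p=0.1, fp=0.1), rng_seed=8)
    assert any(
        p.n_bins != q.n_bins or not np.array_equal(p.values, q.values)
        for p, q in zip(data.profiles, other.profiles)
    )


def test_dataset_without_seeds():
    data = simulate_dataset(SimulationParams(n_per_seed=3, include_seeds=False))
    assert data.size == 15


# ---------------------------------------------------------------------------
# multi-class MCC
# ---------------------------------------------------------------------------


def test_rk_known_confusion():
    assert rk_statistic(np.array([[40, 10], [10, 40]])) == pytest.approx(0.6)
    assert rk_statistic(np.diag([10, 20, 30])) == 1.0


def test_mcc_identical_partitions_any_labeling(rng):
    labels = rng.integers(1, 6, size=300)
    relabel = {1: 40, 2: 7, 3: 99, 4: 0, 5: 13}
    shuffled = np.array([relabel[l] for l in labels])
    assert mcc_multiclass(labels, shuffled) == pytest.approx(1.0)


def test_mcc_random_clusters_small_positive(rng):
    """Random clusterings score near zero.  The optimal label matching step
    maximizes the diagonal, so the null mean carries a small positive bias
    rather than sitting exactly at zero; it must stay far below real signal."""
    labels = np.repeat(np.arange(1, 6), 100)
    vals = [
        mcc_multiclass(labels, rng.integers(0, 5, size=500)) for _ in range(1000)
    ]
    assert 0.0 < np.mean(vals) < 0.1
    assert max(vals) < 0.3


def test_mcc_invariant_to_relabeling(rng):
    labels = rng.integers(1, 6, size=200)
    clusters = rng.integers(0, 5, size=200)
    base = mcc_multiclass(labels, clusters)
    perm = rng.permutation(5)
    assert mcc_multiclass(labels, perm[clusters]) == pytest.approx(base)


def test_mcc_validation():
    with pytest.raises(ValueError):
        mcc_multiclass([1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        mcc_multiclass([1, 1, 1], [1, 2, 1])


def test_mcc_handles_unequal_cluster_count():
    labels = [1, 1, 2, 2, 3, 3]
    assert mcc_multiclass(labels, [0, 0, 1, 1, 1, 1]) < 1.0


# ---------------------------------------------------------------------------
# benchmark pipelines (small smoke; full criteria live in test_acceptance)
# ---------------------------------------------------------------------------


def test_pipelines_recover_clean_classes():
    data = simulate_dataset(SimulationParams(v=0, p=0, fp=0.1, n_per_seed=9), rng_seed=0)
    assert mcc_multiclass(data.labels, cluster_labels_dgw(data, 5)) == pytest.approx(1.0)
    assert mcc_multiclass(data.labels, cluster_labels_baseline(data, 5)) == pytest.approx(1.0)


def test_benchmark_grid_shape(tmp_path):
    grid = run_benchmark_grid(
        v_values=(0.0, 0.1), p_values=(0.0,), fp=0.1, n_per_seed=5, rng_seed=1
    )
    assert list(grid.columns) == ["v", "p", "mcc_dgw", "mcc_baseline"]
    assert len(grid) == 2
    assert ((grid[["mcc_dgw", "mcc_baseline"]] <= 1.0) & (grid[["mcc_dgw", "mcc_baseline"]] >= -1.0)).all().all()
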