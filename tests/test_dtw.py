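"""Unit and property tests for the warping core."""

import numpy as np
import pytest

from peakwarp.dtw import (
    AlignmentResult,
    DtwConfig,
    WarpingPath,
    accumulated_cost_matrix,
    dtw_align,
    flip_aware_distance,
    local_distance,
)

from conftest import brute_dtw


# ---------------------------------------------------------------------------
# config and local distance
# ---------------------------------------------------------------------------


def test_config_rejects_bad_values():
    with pytest.raises(ValueError):
        DtwConfig(metric="euclidean")
    with pytest.raises(ValueError):
        DtwConfig(band_width=-1)
    with pytest.raises(ValueError):
        DtwConfig(stretch_penalty=0.5)


def test_local_distance_sqeuclidean():
    assert local_distance(3.0, 1.0) == 4.0
    assert local_distance([1.0, 2.0], [3.0, 0.0]) == 8.0


def test_local_distance_cosine_conventions():
    assert local_distance([1.0, 0.0], [0.0, 1.0], metric="cosine") == pytest.approx(1.0)
    assert local_distance([1.0, 1.0], [2.0, 2.0], metric="cosine") == pytest.approx(0.0)
    assert local_distance([0.0, 0.0], [0.0, 0.0], metric="cosine") == 0.0
    assert local_distance([0.0, 0.0], [1.0, 2.0], metric="cosine") == 1.0


def test_local_distance_shape_mismatch():
    with pytest.raises(ValueError):
        local_distance([1.0, 2.0], [1.0])


# ---------------------------------------------------------------------------
# alignment basics
# ---------------------------------------------------------------------------


def test_identical_sequences_align_diagonally():
    a = np.array([1.0, 5.0, 2.0, 8.0])
    res = dtw_align(a, a)
    assert res.distance == 0.0
    assert np.array_equal(res.path.pairs, np.column_stack([np.arange(4), np.arange(4)]))


def test_path_contract_random(rng):
    for _ in range(50):
        n, m = rng.integers(1, 12, size=2)
        a = rng.random(int(n)) * 10
        b = rng.random(int(m)) * 10
        res = dtw_align(a, b)
        res.path.validate(int(n), int(m))  # endpoints pinned, unit steps
        # every index of both sequences occurs on the path
        assert set(res.path.pairs[:, 0]) == set(range(int(n)))
        assert set(res.path.pairs[:, 1]) == set(range(int(m)))


def test_path_cost_reproduces_distance(rng):
    for gamma in (1.0, 2.5):
        for _ in range(25):
            n, m = rng.integers(2, 10, size=2)
            a = rng.random(int(n)) * 5
            b = rng.random(int(m)) * 5
            cfg = DtwConfig(stretch_penalty=gamma)
            res = dtw_align(a, b, cfg)
            cost = (a[res.path.pairs[0, 0]] - b[res.path.pairs[0, 1]]) ** 2
            run = 0
            for prev, cur in zip(res.path.pairs, res.path.pairs[1:]):
                di, dj = cur - prev
                run = 0 if (di == 1 and dj == 1) else run + 1
                cost += (a[cur[0]] - b[cur[1]]) ** 2 * gamma ** min(run, 8)
            assert cost == pytest.approx(res.distance, rel=1e-10, abs=1e-10)


def test_symmetry(rng):
    """Unbanded kernels are exactly symmetric in their arguments.  The banded
    kernel is excluded: the slanted corridor j ~ i*M/N is only transpose-
    symmetric up to integer rounding, so d(a,b) and d(b,a) may differ when
    lengths are unequal."""
    for cfg in (DtwConfig(), DtwConfig(stretch_penalty=2.0)):
        for _ in range(20):
            n, m = rng.integers(2, 15, size=2)
            a = rng.random(int(n)) * 10
            b = rng.random(int(m)) * 10
            assert dtw_align(a, b, cfg).distance == pytest.approx(
                dtw_align(b, a, cfg).distance, rel=1e-12
            )


def test_band_monotonicity(rng):
    """Narrowing the corridor can only keep or increase the optimum."""
    for _ in range(20):
        a = rng.random(20) * 10
        b = rng.random(16) * 10
        prev = -np.inf
        for band in (12, 8, 5, 3, 1):
            d = dtw_align(a, b, DtwConfig(band_width=band)).distance
            assert d >= prev - 1e-12
            prev = d
    # band 0 (off) is the unconstrained optimum
    d_off = dtw_align(a, b, DtwConfig(band_width=0)).distance
    assert d_off <= dtw_align(a, b, DtwConfig(band_width=1)).distance + 1e-12


def test_band_always_feasible_for_unequal_lengths():
    a = np.ones(30)
    b = np.ones(5)
    res = dtw_align(a, b, DtwConfig(band_width=1))
    assert np.isfinite(res.distance)
    res.path.validate(30, 5)


def test_stretch_penalty_monotone(rng):
    """A larger gamma can only keep or increase the optimal cost."""
    for _ in range(15):
        a = rng.random(12) * 10
        b = rng.random(9) * 10
        ds = [
            dtw_align(a, b, DtwConfig(stretch_penalty=g)).distance
            for g in (1.0, 1.5, 2.5, 4.0)
        ]
        assert all(d2 >= d1 - 1e-12 for d1, d2 in zip(ds, ds[1:]))


def test_stretch_penalty_equal_lengths_identity():
    """For identical sequences the diagonal path is free regardless of gamma."""
    a = np.array([4.0, 1.0, 7.0, 3.0])
    assert dtw_align(a, a, DtwConfig(stretch_penalty=3.0)).distance == 0.0


# ---------------------------------------------------------------------------
# oracle equivalence (small cases, all knobs)
# ---------------------------------------------------------------------------


def test_oracle_plain_small(rng):
    for _ in range(200):
        n, m = rng.integers(1, 7, size=2)
        a = np.round(rng.random(int(n)) * 10, 3)
        b = np.round(rng.random(int(m)) * 10, 3)
        got = dtw_align(a, b).distance
        want = brute_dtw(a, b)
        assert got == pytest.approx(want, rel=1e-12, abs=1e-12)


def test_oracle_with_band(rng):
    for _ in range(100):
        n, m = rng.integers(2, 7, size=2)
        a = rng.random(int(n)) * 10
        b = rng.random(int(m)) * 10
        band = int(rng.integers(1, 4))
        got = dtw_align(a, b, DtwConfig(band_width=band)).distance
        want = brute_dtw(a, b, band=band)
        assert got == pytest.approx(want, rel=1e-12, abs=1e-12)


def test_oracle_with_stretch_penalty(rng):
    for gamma in (1.5, 2.5, 4.0):
        for _ in range(60):
            n, m = rng.integers(2, 7, size=2)
            a = rng.random(int(n)) * 10
            b = rng.random(int(m)) * 10
            got = dtw_align(a, b, DtwConfig(stretch_penalty=gamma)).distance
            want = brute_dtw(a, b, gamma=gamma)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12)


def test_oracle_multitrack_cosine(rng):
    for _ in range(60):
        n, m = rng.integers(2, 6, size=2)
        a = rng.random((int(n), 2)) * 10
        b = rng.random((int(m), 2)) * 10
        got = dtw_align(a, b, DtwConfig(metric="cosine")).distance
        want = brute_dtw(a, b, metric="cosine")
        assert got == pytest.approx(want, rel=1e-10, abs=1e-10)


# ---------------------------------------------------------------------------
# flip awareness
# ---------------------------------------------------------------------------


def test_flip_detects_reversal(rng):
    a = np.array([0.0, 1.0, 5.0, 9.0, 3.0, 0.5, 0.0])
    res = flip_aware_distance(a, a[::-1])
    assert res.flipped
    assert res.distance == 0.0


def test_flip_tie_prefers_unflipped():
    a = np.array([1.0, 2.0, 1.0])  # palindromic: both orientations tie
    res = flip_aware_distance(a, a)
    assert not res.flipped
    assert res.distance == 0.0


def test_flip_aware_is_min_of_orientations(rng):
    for _ in range(20):
        a = rng.random(10) * 10
        b = rng.random(8) * 10
        fwd = dtw_align(a, b).distance
        rev = dtw_align(a, b[::-1]).distance
        res = flip_aware_distance(a, b)
        assert res.distance == pytest.approx(min(fwd, rev), rel=1e-12)
        assert res.flipped == (rev < fwd)


def test_flip_aware_disabled():
    a = np.array([0.0, 1.0, 5.0, 9.0])
    res = flip_aware_distance(a, a[::-1], DtwConfig(flip_aware=False))
    assert not res.flipped
    assert res.distance > 0


# ---------------------------------------------------------------------------
# normalization and the scalar-cosine fallback
# ---------------------------------------------------------------------------


def test_height_normalization_removes_scale():
    a = np.array([1.0, 4.0, 2.0])
    cfg = DtwConfig(normalize_heights=True)
    assert dtw_align(a, 100 * a, cfg).distance == pytest.approx(0.0)


def test_normalization_rejects_zero_track():
    with pytest.raises(ValueError):
        dtw_align(np.zeros(4), np.ones(4), DtwConfig(normalize_heights=True))


def test_scalar_cosine_falls_back_with_warning():
    a = np.array([1.0, 4.0, 2.0])
    b = np.array([2.0, 8.0, 4.0])
    with pytest.warns(UserWarning, match="degenerate"):
        res = dtw_align(a, b, DtwConfig(metric="cosine"))
    # fallback = squared Euclidean on height-normalized values
    expected = dtw_align(a, b, DtwConfig(normalize_heights=True)).distance
    assert res.distance == pytest.approx(expected)


def test_multitrack_cosine_no_warning(recwarn, rng):
    a = rng.random((5, 2))
    b = rng.random((6, 2))
    dtw_align(a, b, DtwConfig(metric="cosine"))
    assert not [w for w in recwarn.list if "degenerate" in str(w.message)]


# ---------------------------------------------------------------------------
# errors and misc
# ---------------------------------------------------------------------------


def test_empty_and_mismatched_inputs():
    with pytest.raises(ValueError):
        dtw_align(np.array([]), np.array([1.0]))
    with pytest.raises(ValueError):
        dtw_align(np.ones((3, 2)), np.ones((3, 3)))


def test_accumulated_cost_matrix_corner_is_distance(rng):
    for cfg in (DtwConfig(), DtwConfig(band_width=4), DtwConfig(stretch_penalty=2.0)):
        a = rng.random(9) * 10
        b = rng.random(7) * 10
        acc = accumulated_cost_matrix(a, b, cfg)
        assert acc.shape == (9, 7)
        assert acc[-1, -1] == pytest.approx(dtw_align(a, b, cfg).distance, rel=1e-12)


def test_warping_path_validation():
    with pytest.raises(ValueError):
        WarpingPath(np.array([[0, 0], [2, 1]])).validate(3, 2)  # step of 2
    with pytest.raises(ValueError):
        WarpingPath(np.array([[0, 0], [1, 1]])).validate(3, 2)  # endpoint not pinned


def test_accepts_profile_objects():
    from peakwarp.profiles import Profile, Region

    p1 = Profile(Region("chr1", 0, 200, "a"), np.array([1.0, 2.0, 3.0, 2.0]), 50)
    p2 = Profile(Region("chr1", 0, 200, "b"), np.array([1.0, 2.0, 3.0, 2.0]), 50)
    assert dtw_align(p1, p2).distance == 0.0
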