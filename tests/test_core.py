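"""Integral images and the neighborhood threshold against brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ndnt.core import (
    NDNTParams,
    integral_image,
    ndnt_threshold,
    ndnt_threshold_2d_stack,
    ndnt_tiled,
    threshold_sweep,
    window_sum,
)

from conftest import brute_ndnt, brute_neighborhood_stats, brute_prefix_sums


class TestIntegralImage:
    def test_all_ones_total_is_voxel_count(self):
        ii = integral_image(np.ones((2, 2, 2), dtype=np.uint8))
        assert ii[-1, -1, -1] == 8

    def test_first_entry_is_first_voxel(self, rng):
        v = rng.integers(0, 256, size=(3, 4, 5)).astype(np.uint8)
        ii = integral_image(v)
        assert ii[1, 1, 1] == v[0, 0, 0]

    def test_matches_brute_force_prefix_sums(self, rng):
        v = rng.integers(0, 256, size=(4, 5, 6)).astype(np.uint8)
        ii = integral_image(v)
        assert np.array_equal(ii[1:, 1:, 1:], brute_prefix_sums(v))

    def test_monotone_for_nonnegative_input(self, rng):
        ii = integral_image(rng.integers(0, 256, size=(5, 6)).astype(np.uint16))
        for ax in range(ii.ndim):
            assert (np.diff(ii, axis=ax) >= 0).all()

    def test_no_overflow_on_uniform_255_cube(self):
        v = np.full((64, 64, 64), 255, dtype=np.uint8)
        ii = integral_image(v)
        assert int(ii[-1, -1, -1]) == 255 * 64**3

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError):
            integral_image(np.empty((0, 3)))


class TestWindowSum:
    def test_interior_window_on_ones(self):
        ii = integral_image(np.ones((5, 5)))
        assert window_sum(ii, (2, 2), (3, 3)) == (9, 9)

    def test_corner_window_clips(self):
        ii = integral_image(np.ones((5, 5)))
        assert window_sum(ii, (0, 0), (3, 3)) == (4, 4)

    def test_even_window_extends_to_lower_indices(self):
        v = np.arange(25).reshape(5, 5)
        ii = integral_image(v)
        s, c = window_sum(ii, (2, 2), (2, 2))
        # rows/cols 1..2 inclusive
        assert c == 4 and s == v[1:3, 1:3].sum()

    def test_random_centers_match_brute_force(self, rng):
        v = rng.integers(0, 256, size=(6, 7, 8)).astype(np.int32)
        ii = integral_image(v)
        win = (3, 5, 3)
        for _ in range(50):
            c = tuple(int(rng.integers(0, n)) for n in v.shape)
            lo = [max(i - w // 2, 0) for i, w in zip(c, win)]
            hi = [min(i - w // 2 + w, n) for i, w, n in zip(c, win, v.shape)]
            expected = v[tuple(slice(a, b) for a, b in zip(lo, hi))]
            s, cnt = window_sum(ii, c, win)
            assert s == expected.sum() and cnt == expected.size

    def test_out_of_bounds_center_rejected(self):
        ii = integral_image(np.ones((4, 4)))
        with pytest.raises(IndexError):
            window_sum(ii, (4, 0), (3, 3))


class TestNdntThreshold:
    def test_uniform_volume_yields_empty_mask_at_positive_t(self):
        v = np.full((6, 6, 6), 37, dtype=np.uint8)
        mask = ndnt_threshold(v, NDNTParams((3, 3, 3), 5, "dark_foreground"))
        assert not mask.any()

    def test_uniform_volume_fully_foreground_at_t_zero(self):
        # at t=0 the inclusive rule marks voxels at-or-below the local mean
        v = np.full((6, 6), 37, dtype=np.uint8)
        mask = ndnt_threshold(v, NDNTParams((3, 3), 0, "dark_foreground"))
        assert mask.all()

    def test_single_dark_pixel_in_bright_field(self):
        v = np.full((9, 9), 200, dtype=np.uint8)
        v[4, 4] = 10
        params = NDNTParams((3, 3), 10, "dark_foreground")
        mask = ndnt_threshold(v, params)
        assert np.array_equal(mask, brute_ndnt(v, params))
        assert mask[4, 4] and mask.sum() == 1

    @pytest.mark.parametrize("t", [2, 10, 25])
    @pytest.mark.parametrize("polarity", ["dark_foreground", "bright_foreground"])
    def test_matches_brute_force_3d(self, rng, t, polarity):
        v = rng.integers(0, 256, size=(16, 16, 8)).astype(np.uint8)
        params = NDNTParams((5, 5, 3), t, polarity)
        assert np.array_equal(ndnt_threshold(v, params), brute_ndnt(v, params))

    def test_matches_brute_force_float_input(self, rng):
        v = rng.random((10, 12))
        params = NDNTParams((5, 3), 10, "dark_foreground")
        assert np.array_equal(ndnt_threshold(v, params), brute_ndnt(v, params))

    def test_corner_voxel_uses_clipped_count(self):
        # hand-computed corner decision on a 4x4 ramp, window 3x3
        v = np.arange(16, dtype=np.int64).reshape(4, 4)
        mask = ndnt_threshold(v, NDNTParams((3, 3), 10, "dark_foreground"))
        box = v[:2, :2]  # clipped corner box: 4 voxels
        assert mask[0, 0] == (v[0, 0] * box.size * 100 <= box.sum() * 90)

    def test_monotone_nesting_in_t(self, rng):
        v = rng.integers(0, 256, size=(12, 14)).astype(np.uint8)
        prev = None
        for t in (0, 5, 15, 40, 80):
            m = ndnt_threshold(v, NDNTParams((5, 5), t, "dark_foreground"))
            if prev is not None:
                assert not (m & ~prev).any()  # foreground shrinks as t grows
            prev = m

    def test_scale_invariance(self, rng):
        v = rng.random((10, 10, 6)) + 0.1
        for pol in ("dark_foreground", "bright_foreground"):
            p = NDNTParams((3, 5, 3), 12.5, pol)
            assert np.array_equal(ndnt_threshold(v, p), ndnt_threshold(2.0 * v, p))

    def test_window_larger_than_volume_rejected(self):
        with pytest.raises(ValueError):
            ndnt_threshold(np.ones((4, 4)), NDNTParams((5, 3), 10))

    def test_nan_rejected(self):
        v = np.ones((4, 4))
        v[0, 0] = np.nan
        with pytest.raises(ValueError):
            ndnt_threshold(v, NDNTParams((3, 3), 10))

    def test_invalid_t_rejected(self):
        with pytest.raises(ValueError):
            NDNTParams((3, 3), 101)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        t=st.sampled_from([0, 2, 10, 25, 50]),
        polarity=st.sampled_from(["dark_foreground", "bright_foreground"]),
    )
    def test_oracle_equivalence_property(self, seed, t, polarity):
        r = np.random.default_rng(seed)
        shape = tuple(int(r.integers(4, 13)) for _ in range(int(r.integers(2, 4))))
        v = r.integers(0, 256, size=shape).astype(np.uint8)
        win = tuple(int(r.integers(1, min(n, 5) + 1)) for n in shape)
        params = NDNTParams(win, t, polarity)
        assert np.array_equal(ndnt_threshold(v, params), brute_ndnt(v, params))


class TestStackAndTiled:
    def test_2d_stack_equals_3d_with_unit_z_window(self, rng):
        v = rng.integers(0, 256, size=(6, 20, 18)).astype(np.uint8)
        p2 = NDNTParams((7, 7), 10)
        p3 = NDNTParams((1, 7, 7), 10)
        assert np.array_equal(ndnt_threshold_2d_stack(v, p2), ndnt_threshold(v, p3))

    def test_single_slice_stack_equals_2d(self, rng):
        v = rng.integers(0, 256, size=(1, 15, 15)).astype(np.uint8)
        out = ndnt_threshold_2d_stack(v, NDNTParams((5, 5), 10))
        assert np.array_equal(out[0], ndnt_threshold(v[0], NDNTParams((5, 5), 10)))

    def test_per_slice_matches_brute_force(self, rng):
        v = rng.integers(0, 256, size=(8, 32, 32)).astype(np.uint8)
        out = ndnt_threshold_2d_stack(v, NDNTParams((7, 7), 10))
        for z in range(v.shape[0]):
            assert np.array_equal(out[z], brute_ndnt(v[z], NDNTParams((7, 7), 10)))

    def test_tile_equal_to_volume_matches_untiled(self, rng):
        v = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        p = NDNTParams((5, 5), 10, tile_shape=(16, 16))
        assert np.array_equal(ndnt_tiled(v, p), ndnt_threshold(v, NDNTParams((5, 5), 10)))

    def test_tiles_match_per_tile_oracle(self, rng):
        v = rng.integers(0, 200, size=(16, 16)).astype(np.int32)
        v[8:, 8:] += 50  # one quadrant with a grayscale offset
        p = NDNTParams((5, 5), 10, tile_shape=(8, 8))
        out = ndnt_tiled(v, p)
        for i in (0, 8):
            for j in (0, 8):
                tile = v[i : i + 8, j : j + 8]
                expected = ndnt_threshold(tile, NDNTParams((5, 5), 10))
                assert np.array_equal(out[i : i + 8, j : j + 8], expected)

    def test_3d_tiles_match_per_tile_oracle(self, rng):
        v = rng.integers(0, 256, size=(16, 16, 16)).astype(np.uint8)
        for tile in ((8, 8, 8), (16, 16, 16)):
            p = NDNTParams((3, 3, 3), 10, tile_shape=tile)
            out = ndnt_tiled(v, p)
            for zs in range(0, 16, tile[0]):
                for ys in range(0, 16, tile[1]):
                    for xs in range(0, 16, tile[2]):
                        block = v[zs : zs + tile[0], ys : ys + tile[1], xs : xs + tile[2]]
                        exp = ndnt_threshold(block, NDNTParams((3, 3, 3), 10))
                        got = out[zs : zs + tile[0], ys : ys + tile[1], xs : xs + tile[2]]
                        assert np.array_equal(got, exp)

    def test_tile_smaller_than_window_rejected(self):
        with pytest.raises(ValueError):
            NDNTParams((5, 5), 10, tile_shape=(4, 8))


class TestThresholdSweep:
    def test_single_row_fraction_in_unit_interval(self, rng):
        v = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        df = threshold_sweep(v, [NDNTParams((5, 5), 10)])
        assert len(df) == 1 and 0.0 <= df.foreground_fraction[0] <= 1.0

    def test_exact_match_scores_zero_and_ranks_first(self, rng):
        # two dark squares of different depth: the weak one is only picked
        # up at low t, so the three masks are pairwise distinct
        v = np.full((12, 24), 200, dtype=np.uint8)
        v[4:8, 3:7] = 60
        v[4:8, 15:19] = 175
        grid = [NDNTParams((5, 5), t) for t in (5, 30, 80)]
        masks = [ndnt_threshold(v, p) for p in grid]
        assert not np.array_equal(masks[0], masks[1]) and not np.array_equal(masks[1], masks[2])
        df = threshold_sweep(v, grid, reference=masks[1])
        assert df.score[0] == 0.0 and df.t[0] == 30

    def test_reference_shape_mismatch_rejected(self, rng):
        v = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        with pytest.raises(ValueError):
            threshold_sweep(v, [NDNTParams((3, 3), 10)], reference=np.zeros((9, 9), bool))

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            threshold_sweep(np.ones((4, 4)), [])
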