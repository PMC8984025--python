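"""Aggregation, tiling, temporal stacking, fold geometry, and map assembly."""

import numpy as np
import pytest

from paddy.errors import ConfigurationError, InputError
from paddy.prep import (
    FOLD_IDS,
    aggregate,
    assemble_map,
    difference_map,
    partition_folds,
    select_tiles,
    stack_time,
    tile,
)
from paddy.rasters import FEATURE_NAMES, FeatureRaster, YieldRaster


def make_rasters(h=20, w=20, rng=None):
    rng = rng or np.random.default_rng(0)
    data = rng.normal(size=(7, h, w))
    mask = np.ones((h, w), bool)
    return FeatureRaster(data, mask.copy()), YieldRaster(
        rng.normal(9, 0.9, (h, w)), mask.copy()
    )


class TestAggregate:
    def test_constant_block(self):
        out, mask = aggregate(np.ones((10, 10)), 10)
        assert out.shape == (1, 1) and out[0, 0] == 1.0 and mask.all()

    def test_factor_one_is_identity(self):
        x = np.arange(12.0).reshape(3, 4)
        out, _ = aggregate(x, 1)
        np.testing.assert_array_equal(out, x)

    def test_matches_brute_force_oracle(self):
        x = np.arange(400.0).reshape(20, 20)
        out, _ = aggregate(x, 10)
        oracle = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                acc = 0.0
                for di in range(10):
                    for dj in range(10):
                        acc += x[10 * i + di, 10 * j + dj]
                oracle[i, j] = acc / 100
        np.testing.assert_allclose(out, oracle)

    def test_commutes_with_affine_transform(self, rng):
        x = rng.normal(size=(30, 40))
        direct, _ = aggregate(3.0 * x + 2.0, 5)
        via, _ = aggregate(x, 5)
        np.testing.assert_allclose(direct, 3.0 * via + 2.0, atol=1e-12)

    def test_masked_cells_excluded_from_mean(self):
        x = np.array([[1.0, 5.0], [3.0, 7.0]])
        mask = np.array([[True, False], [True, False]])
        out, outmask = aggregate(x, 2, mask)
        assert out[0, 0] == 2.0 and outmask[0, 0]
        _, outmask = aggregate(x, 2, np.zeros((2, 2), bool))
        assert not outmask[0, 0]

    def test_partial_blocks_dropped(self):
        out, _ = aggregate(np.ones((23, 21)), 10)
        assert out.shape == (2, 2)

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ConfigurationError):
            aggregate(np.ones((10, 10)), 2.5)


class TestTiling:
    def test_fully_valid_raster_tile_count(self):
        fr, yr = make_rasters(20, 20)
        assert len(tile(fr, yr)) == 16

    def test_single_invalid_pixel_excludes_one_tile(self):
        fr, yr = make_rasters(20, 20)
        yr.mask[7, 7] = False
        ts = tile(fr, yr)
        assert len(ts) == 15
        assert (1, 1) not in set(zip(ts.rows.tolist(), ts.cols.tolist()))

    def test_trailing_remainder_never_tiled(self):
        fr, yr = make_rasters(23, 21)
        ts = tile(fr, yr)
        assert ts.grid_shape == (4, 4) and len(ts) == 16

    def test_shape_mismatch_rejected(self):
        fr, _ = make_rasters(20, 20)
        _, yr = make_rasters(25, 20)
        with pytest.raises(InputError):
            tile(fr, yr)

    def test_feature_and_yield_masks_are_comasked(self):
        fr, yr = make_rasters(10, 10)
        fr.mask[0, 0] = False
        yr.mask[9, 9] = False
        ts = tile(fr, yr)
        assert len(ts) == 2  # both corner tiles dropped


class TestStackTime:
    def test_identical_dates_constant_along_time(self):
        fr, yr = make_rasters(20, 20)
        single = tile(fr, yr)
        temporal = stack_time([single] * 5)
        assert temporal.features.shape == (16, 5, 5, 5, 7)
        assert np.ptp(temporal.features, axis=3).max() == 0

    def test_tile_missing_at_one_date_is_dropped(self):
        fr1, yr = make_rasters(20, 20)
        fr2, _ = make_rasters(20, 20)
        fr2.mask[0, 0] = False
        t1, t2 = tile(fr1, yr), tile(fr2, yr)
        temporal = stack_time([t1, t2])
        assert len(temporal) == 15

    def test_single_date_is_axis_insertion(self):
        fr, yr = make_rasters(20, 20)
        single = tile(fr, yr)
        temporal = stack_time([single])
        np.testing.assert_array_equal(temporal.features[:, :, :, 0, :], single.features)
        np.testing.assert_array_equal(temporal.yields, single.yields)


class TestFolds:
    def test_fractions_on_20x20_grid(self):
        fr, yr = make_rasters(100, 100)  # 20x20 tile grid
        ts = tile(fr, yr)
        for fold in partition_folds(ts):
            frac = fold.fractions()
            assert abs(frac["train"] - 0.50) <= 0.05
            assert abs(frac["validation"] - 0.25) <= 0.05
            assert abs(frac["test"] - 0.25) <= 0.05

    def test_deterministic(self):
        fr, yr = make_rasters(100, 100)
        ts = tile(fr, yr)
        a = partition_folds(ts)
        b = partition_folds(ts)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.role_grid, fb.role_grid)

    def test_test_regions_cover_the_field(self):
        fr, yr = make_rasters(100, 100)
        ts = tile(fr, yr)
        retained = ts.retained_grid()
        covered = np.zeros_like(retained)
        for fold in partition_folds(ts):
            covered |= fold.role_grid == "test"
        assert (covered & retained).sum() / retained.sum() >= 0.95

    def test_roles_are_disjoint_within_fold(self):
        fr, yr = make_rasters(100, 100)
        ts = tile(fr, yr)
        for fold in partition_folds(ts):
            train = fold.role_grid == "train"
            val = fold.role_grid == "validation"
            test = fold.role_grid == "test"
            assert not (train & val).any()
            assert not (train & test).any()
            assert not (val & test).any()

    def test_roles_partition_retained_tiles(self):
        fr, yr = make_rasters(100, 100)
        yr.mask[3, 3] = False
        ts = tile(fr, yr)
        for fold in partition_folds(ts):
            counts = fold.role_counts()
            assert sum(counts.values()) == len(ts)

    def test_each_role_is_contiguous_row_band(self):
        fr, yr = make_rasters(100, 100)
        ts = tile(fr, yr)
        for fold in partition_folds(ts):
            for role in ("test", "validation"):
                rows = np.nonzero((fold.role_grid == role).any(axis=1))[0]
                assert (np.diff(rows) == 1).all()

    def test_too_small_grid_rejected(self):
        fr, yr = make_rasters(15, 15)  # 3x3 tile grid
        with pytest.raises(ConfigurationError):
            partition_folds(tile(fr, yr))

    def test_fold_ids(self):
        fr, yr = make_rasters(100, 100)
        ts = tile(fr, yr)
        assert tuple(f.fold_id for f in partition_folds(ts)) == FOLD_IDS


class TestAssembly:
    def test_round_trip_is_identity_on_retained_extents(self):
        fr, yr = make_rasters(20, 20)
        yr.mask[0, 0] = False
        ts = tile(fr, yr)
        rebuilt = assemble_map(ts, ts.yields)
        np.testing.assert_array_equal(
            rebuilt.values[rebuilt.mask], yr.values[rebuilt.mask]
        )
        assert not rebuilt.mask[:5, :5].any()  # excluded tile is nodata

    def test_single_tile_leaves_rest_nodata(self):
        fr, yr = make_rasters(20, 20)
        ts = tile(fr, yr).subset(np.array([0]))
        rebuilt = assemble_map(ts, ts.yields)
        assert rebuilt.mask.sum() == 25

    def test_missing_prediction_rejected(self):
        fr, yr = make_rasters(20, 20)
        ts = tile(fr, yr)
        with pytest.raises(InputError):
            assemble_map(ts, ts.yields[:-1])

    def test_difference_map_sign_convention(self):
        fr, yr = make_rasters(20, 20)
        ts = tile(fr, yr)
        observed = assemble_map(ts, ts.yields)
        predicted = assemble_map(ts, ts.yields - 1.0)
        diff = difference_map(observed, predicted)
        # observed minus predicted: underprediction is positive
        np.testing.assert_allclose(diff.values[diff.mask], 1.0)


def test_select_tiles_matches_role_grid():
    fr, yr = make_rasters(100, 100)
    ts = tile(fr, yr)
    fold = partition_folds(ts)[0]
    picked = select_tiles(ts, fold, "test")
    assert all(
        fold.role_grid[r, c] == "test"
        for r, c in zip(picked.rows, picked.cols)
    )
    total = sum(len(select_tiles(ts, fold, r)) for r in ("train", "validation", "test"))
    assert total == len(ts)
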