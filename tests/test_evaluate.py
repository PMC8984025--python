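"""Evaluation metrics against a brute-force oracle; blanking importance."""

import json
import math

import numpy as np
import pytest

from paddy.errors import ConfigurationError, InputError
from paddy.evaluate import (
    EvalReport,
    blank_feature,
    compute_metrics,
    cross_fold_summary,
    evaluate_model,
    feature_importance,
    reports_to_frame,
)
from paddy.models import (
    TileGradientBoostingRegressor,
    TileLinearRegressor,
    TileNullRegressor,
)
from paddy.prep import TileSet
from paddy.rasters import FEATURE_NAMES


def metrics_oracle(obs, pred):
    """Independent plain-python summation of the four printed formulas."""
    n = len(obs)
    sq = sum((o - p) ** 2 for o, p in zip(obs, pred))
    rmse = math.sqrt(sq / n)
    mae = sum(abs(p - o) for o, p in zip(obs, pred)) / n
    mbe = sum(p - o for o, p in zip(obs, pred)) / n
    mo = sum(obs) / n
    mp = sum(pred) / n
    num = sum((o - mo) * (p - mp) for o, p in zip(obs, pred))
    do = sum((o - mo) ** 2 for o in obs)
    dp = sum((p - mp) ** 2 for p in pred)
    r2 = None if do == 0 or dp == 0 else num**2 / (do * dp)
    return rmse, mae, mbe, r2


def make_tiles(features, yields):
    n = len(features)
    side = int(np.ceil(np.sqrt(n)))
    rows, cols = np.divmod(np.arange(n), side)
    return TileSet(
        features=features, yields=yields, rows=rows, cols=cols,
        grid_shape=(side, side), field_shape=(side * 5, side * 5),
    )


class TestComputeMetrics:
    def test_perfect_prediction(self):
        r = compute_metrics([1, 2, 3], [1, 2, 3])
        assert (r.rmse, r.mae, r.mbe, r.r2) == (0.0, 0.0, 0.0, 1.0)

    def test_constant_series_has_undefined_r2(self):
        r = compute_metrics([0.0, 0.0], [1.0, 1.0])
        assert r.rmse == 1.0 and r.mae == 1.0 and r.mbe == 1.0
        assert r.r2 is None

    def test_overprediction_is_positive_bias(self):
        r = compute_metrics([5.0, 5.0, 6.0], [6.0, 6.0, 7.0])
        assert r.mbe == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            obs = rng.normal(9, 1, 100)
            pred = obs + rng.normal(0, 0.5, 100)
            r = compute_metrics(obs, pred)
            rmse, mae, mbe, r2 = metrics_oracle(obs.tolist(), pred.tolist())
            assert r.rmse == pytest.approx(rmse, abs=1e-12)
            assert r.mae == pytest.approx(mae, abs=1e-12)
            assert r.mbe == pytest.approx(mbe, abs=1e-12)
            assert r.r2 == pytest.approx(r2, abs=1e-12)

    def test_jensen_inequalities(self, rng):
        obs = rng.normal(9, 1, 1000)
        pred = obs + rng.normal(0, 0.3, 1000)
        r = compute_metrics(obs, pred)
        assert r.mae <= r.rmse
        assert abs(r.mbe) <= r.mae

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            compute_metrics([1, 2], [1, 2, 3])

    def test_rrmse_approaches_null_as_predictions_approach_mean(self, rng):
        obs = rng.normal(9, 0.9, 2000)
        null_rrmse = compute_metrics(obs, np.full_like(obs, obs.mean())).rrmse
        prev = np.inf
        for eps in (0.5, 0.05, 0.005):
            pred = obs.mean() + eps * rng.normal(size=obs.size)
            gap = abs(compute_metrics(obs, pred).rrmse - null_rrmse)
            assert gap < prev + 1e-9
            prev = gap
        assert gap < 0.05


class TestBlanking:
    def _tiles(self, rng, n=40):
        return make_tiles(
            rng.normal(size=(n, 5, 5, 7)), rng.normal(9, 0.9, (n, 5, 5))
        )

    def test_blanking_constant_feature_is_identity(self, rng):
        tiles = self._tiles(rng)
        tiles.features[..., 2] = 1.5
        out = blank_feature(tiles, "NAVI")
        np.testing.assert_array_equal(out.features, tiles.features)

    def test_blanked_layer_mean_is_preserved(self, rng):
        tiles = self._tiles(rng)
        out = blank_feature(tiles, "NDVI")
        idx = FEATURE_NAMES.index("NDVI")
        assert out.features[..., idx].std() == 0
        assert out.features[..., idx].mean() == pytest.approx(
            tiles.features[..., idx].mean()
        )

    def test_null_model_is_blind_to_blanking(self, rng):
        tiles = self._tiles(rng)
        model = TileNullRegressor().fit(tiles.features, tiles.yields)
        for res in feature_importance(model, tiles):
            assert res.delta_rmse == 0.0

    def test_unknown_feature_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            blank_feature(self._tiles(rng), "EVI")


class TestImportance:
    def _single_signal(self, seed, n=400):
        """Yield depends only on CIgreen; all other features pure noise."""
        rng = np.random.default_rng(seed)
        feats = rng.normal(size=(n, 5, 5, 7))
        ci = FEATURE_NAMES.index("CIgreen")
        yields = 9.0 + 0.9 * feats[..., ci] + rng.normal(0, 0.05, (n, 5, 5))
        return make_tiles(feats, yields)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_single_signal_recovery(self, seed):
        tiles = self._single_signal(seed)
        half = len(tiles) // 2
        train = tiles.subset(np.arange(half))
        test = tiles.subset(np.arange(half, len(tiles)))
        model = TileGradientBoostingRegressor(seed=seed).fit(
            train.features, train.yields
        )
        null = TileNullRegressor().fit(train.features, train.yields)
        results = feature_importance(model, test)
        by_feature = {r.feature: r for r in results}
        top = max(results, key=lambda r: r.delta_rmse)
        assert top.feature == "CIgreen"
        # blanking the only informative feature collapses to the null model
        blanked_rmse = (
            evaluate_model(model, blank_feature(test, "CIgreen")).rmse
        )
        null_rmse = evaluate_model(null, test).rmse
        assert blanked_rmse == pytest.approx(null_rmse, rel=0.10)
        # a pure-noise feature barely moves the needle
        assert abs(by_feature["TGI"].delta_rrmse) < 1.0

    def test_blanking_everything_removes_all_information(self):
        tiles = self._single_signal(3)
        half = len(tiles) // 2
        train = tiles.subset(np.arange(half))
        test = tiles.subset(np.arange(half, len(tiles)))
        model = TileLinearRegressor().fit(train.features, train.yields)
        all_blanked = blank_feature(test, list(FEATURE_NAMES))
        pred = model.predict(all_blanked.features)
        assert np.ptp(pred) == pytest.approx(0, abs=1e-9)
        rmse_all = evaluate_model(model, all_blanked).rmse
        for name in FEATURE_NAMES:
            rmse_one = evaluate_model(model, blank_feature(test, name)).rmse
            # monotone up to the variance contributed by the (near-zero)
            # fitted coefficients of the noise features
            assert rmse_all >= rmse_one - 1e-4


class TestSummary:
    def _report(self, fold, rmse=0.8):
        return EvalReport(
            n=100, rmse=rmse, mae=0.6, mbe=0.1, r2=0.2, rrmse=8.8,
            fold_id=fold, model_kind="cnn2d", date_label="booting",
        )

    def test_identical_folds_have_zero_sd(self):
        reports = [self._report(f) for f in "ABCD"]
        out = cross_fold_summary(reports)
        assert out.loc[0, "rmse_std"] == 0.0
        assert out.loc[0, "rmse_mean"] == pytest.approx(0.8)

    def test_mean_is_arithmetic_average(self):
        reports = [self._report(f, rmse=r) for f, r in zip("ABCD", [0.7, 0.8, 0.9, 1.0])]
        out = cross_fold_summary(reports)
        assert out.loc[0, "rmse_mean"] == pytest.approx(0.85)

    def test_round_trip_through_serialization(self, tmp_path):
        reports = [self._report(f, rmse=r) for f, r in zip("ABCD", [0.7, 0.8, 0.9, 1.0])]
        path = tmp_path / "reports.json"
        path.write_text(json.dumps([r.to_dict() for r in reports]))
        restored = [EvalReport(**d) for d in json.loads(path.read_text())]
        assert cross_fold_summary(restored).equals(cross_fold_summary(reports))

    def test_missing_fold_warns_but_computes(self):
        reports = [self._report(f) for f in "ABC"]
        with pytest.warns(UserWarning, match="incomplete"):
            out = cross_fold_summary(reports)
        assert len(out) == 1

    def test_undefined_r2_becomes_nan_in_frame(self):
        rep = EvalReport(n=10, rmse=1, mae=1, mbe=1, r2=None, rrmse=10)
        frame = reports_to_frame([rep])
        assert np.isnan(frame.loc[0, "r2"])
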