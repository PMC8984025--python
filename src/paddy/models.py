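"""The five competing yield models as scikit-learn-style estimators.

All estimators share one contract: ``fit(X, y)`` takes tile features
``X`` of shape (n, 5, 5, 7) (or (n, 5, 5, n_dates, 7) for the
spatio-temporal network) and yield patches ``y`` of shape (n, 5, 5) in
Mg/ha; ``predict(X)`` returns (n, 5, 5) patches.

* :class:`TileNullRegressor` — predicts the training-pixel mean everywhere.
* :class:`TileLinearRegressor` — per-pixel ordinary least squares on the 7
  features (no spatial context), with explicit detection of aliased
  (rank-deficient) columns.
* :class:`TileGradientBoostingRegressor` — per-pixel gradient-boosted trees
  (eta 0.2, depth 2, 200 rounds, squared error), capturing pairwise feature
  interactions but no spatial context.
* :class:`CNN2DRegressor` / :class:`CNN3DRegressor` — autoencoder-like
  convolutional networks mapping a whole input patch to a 5x5 yield patch;
  trained 50 epochs with Adam/MSE, keeping the weights of the epoch with
  the best validation loss.

Inputs to the networks are standardized per feature on the training fold
(the target likewise, with predictions mapped back to Mg/ha).
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .errors import ConfigurationError, InputError
from .rasters import FEATURE_NAMES

__all__ = [
    "TileNullRegressor",
    "TileLinearRegressor",
    "TileGradientBoostingRegressor",
    "CNN2DRegressor",
    "CNN3DRegressor",
    "build_cnn2d",
    "build_cnn3d",
    "make_model",
    "MODEL_KINDS",
]

MODEL_KINDS = ("null", "linear", "xgboost", "cnn2d", "cnn3d")


def _check_tiles(X, y=None, temporal=False):
    """Validate tile features; ``temporal`` is False (n,s,s,f), True
    (n,s,s,dates,f), or None to accept either layout."""
    X = np.asarray(X, dtype=np.float64)
    if temporal is None:
        if X.ndim not in (4, 5):
            raise InputError(
                f"expected tile features with 4 or 5 axes, got shape {X.shape}"
            )
    else:
        want = 5 if temporal else 4
        if X.ndim != want:
            raise InputError(
                f"expected tile features with {want} axes "
                f"({'n,s,s,dates,f' if temporal else 'n,s,s,f'}), got shape {X.shape}"
            )
    if X.shape[0] == 0:
        raise InputError("empty tile set")
    if y is not None:
        y = np.asarray(y, dtype=np.float64)
        if y.shape != X.shape[:3]:
            raise InputError(f"labels {y.shape} do not match tiles {X.shape[:3]}")
        return X, y
    return X


def _pixels(X):
    """Flatten tile features to a per-pixel design matrix (n_pixels, n_feat)."""
    return X.reshape(-1, X.shape[-1])


class TileNullRegressor(RegressorMixin, BaseEstimator):
    """Constant-layer baseline: the mean training-pixel yield everywhere.

    Ignores the features, so it accepts single-date and temporal tiles
    alike.
    """

    def fit(self, X, y):
        X, y = _check_tiles(X, y, temporal=None)
        self.mean_ = float(np.mean(y))
        self.n_features_in_ = X.shape[-1]
        return self

    def predict(self, X):
        check_is_fitted(self, "mean_")
        X = _check_tiles(X, temporal=None)
        return np.full(X.shape[:3], self.mean_)


class TileLinearRegressor(RegressorMixin, BaseEstimator):
    """Per-pixel ordinary least squares on the 7 features.

    Rank deficiency is detected by QR with column pivoting; aliased columns
    are reported (``aliased_``) and dropped, receiving zero coefficients.
    """

    def __init__(self, feature_names=FEATURE_NAMES):
        self.feature_names = feature_names

    def fit(self, X, y):
        X, y = _check_tiles(X, y)
        A = _pixels(X)
        t = y.ravel()
        n, p = A.shape
        if n < p + 1:
            raise InputError(f"need at least {p + 1} pixels, got {n}")
        # alias detection on centered columns: the intercept is always kept,
        # so a column is aliased iff it is collinear with the others after
        # removing its mean (constants center to zero)
        centered = A - A.mean(axis=0)
        _, r, piv = scipy.linalg.qr(centered, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = (diag.max() if diag.max() > 0 else 1.0) * max(centered.shape) * np.finfo(float).eps
        rank = int((diag > tol).sum())
        keep = np.sort(piv[:rank])
        self.aliased_ = tuple(
            self.feature_names[c] if self.feature_names else int(c)
            for c in np.sort(piv[rank:])
        )
        if self.aliased_:
            warnings.warn(
                f"rank-deficient design: dropping aliased feature(s) "
                f"{self.aliased_}",
                stacklevel=2,
            )
        design = np.column_stack([np.ones(n), A[:, keep]])
        beta_kept, *_ = np.linalg.lstsq(design, t, rcond=None)
        beta = np.zeros(p + 1)
        beta[0] = beta_kept[0]
        beta[1 + keep] = beta_kept[1:]
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = _check_tiles(X)
        flat = _pixels(X) @ self.coef_ + self.intercept_
        return flat.reshape(X.shape[:3])


class TileGradientBoostingRegressor(RegressorMixin, BaseEstimator):
    """Per-pixel gradient-boosted regression trees (XGBoost backend).

    Defaults follow the study protocol: learning rate 0.2, maximum depth 2
    (pairwise interactions only), 200 boosting rounds, squared-error
    objective, no subsampling, base score = training-mean yield.
    """

    def __init__(self, eta=0.2, max_depth=2, n_rounds=200, seed=0):
        self.eta = eta
        self.max_depth = max_depth
        self.n_rounds = n_rounds
        self.seed = seed

    def fit(self, X, y):
        import xgboost as xgb

        X, y = _check_tiles(X, y)
        A = _pixels(X)
        t = y.ravel()
        self.base_score_ = float(np.mean(t))
        self.n_features_in_ = A.shape[1]
        if self.n_rounds == 0:
            self.booster_ = None
            return self
        params = {
            "eta": self.eta,
            "max_depth": self.max_depth,
            "objective": "reg:squarederror",
            "base_score": self.base_score_,
            "subsample": 1.0,
            "colsample_bytree": 1.0,
            "tree_method": "exact",
            "nthread": 1,
            "seed": self.seed,
        }
        self.booster_ = xgb.train(
            params, xgb.DMatrix(A, label=t), num_boost_round=self.n_rounds
        )
        return self

    def predict(self, X):
        import xgboost as xgb

        check_is_fitted(self, "base_score_")
        X = _check_tiles(X)
        if self.booster_ is None:
            return np.full(X.shape[:3], self.base_score_)
        flat = self.booster_.predict(xgb.DMatrix(_pixels(X)))
        return np.asarray(flat, dtype=np.float64).reshape(X.shape[:3])


# ---------------------------------------------------------------------------
# Convolutional networks


def build_cnn2d(rng: np.random.Generator | None = None) -> nn.Sequential:
    """Autoencoder-like 2D network for a (5, 5, 7) input patch.

    Encoder: conv 64@3x3 same -> conv 128@2x2 same -> conv 256@1x1 valid;
    bottleneck: flatten -> dense 256 -> dense 6400 -> reshape (5, 5, 256);
    decoder: conv 128@2x2 same -> conv 64@3x3 same -> conv 1@1x1 same
    (linear).  The 6,400-unit dense layer is what the (5, 5, 256) reshape
    requires.
    """
    rng = rng or np.random.default_rng(0)
    return nn.Sequential(
        [
            nn.Conv2D(7, 64, (3, 3), "same", "relu", rng),
            nn.Conv2D(64, 128, (2, 2), "same", "relu", rng),
            nn.Conv2D(128, 256, (1, 1), "valid", "relu", rng),
            nn.Flatten(),
            nn.Dense(5 * 5 * 256, 256, "relu", rng),
            nn.Dense(256, 6400, "linear", rng),
            nn.Reshape((5, 5, 256)),
            nn.Conv2D(256, 128, (2, 2), "same", "relu", rng),
            nn.Conv2D(128, 64, (3, 3), "same", "relu", rng),
            nn.Conv2D(64, 1, (1, 1), "same", "linear", rng),
        ]
    )


def build_cnn3d(rng: np.random.Generator | None = None) -> nn.Sequential:
    """Spatio-temporal network for a (5, 5, 5 dates, 7) input patch.

    The encoder convolves across space and time — kernels (3,3,3) same,
    (2,2,3) same, then (1,1,5) valid, which collapses the 5-date axis to a
    singleton — after which the tensor is reshaped to (5, 5, 256) and the
    tail is identical to the 2D network.
    """
    rng = rng or np.random.default_rng(0)
    return nn.Sequential(
        [
            nn.Conv3D(7, 64, (3, 3, 3), "same", "relu", rng),
            nn.Conv3D(64, 128, (2, 2, 3), "same", "relu", rng),
            nn.Conv3D(128, 256, (1, 1, 5), "valid", "relu", rng),
            nn.Reshape((5, 5, 256)),
            nn.Flatten(),
            nn.Dense(5 * 5 * 256, 256, "relu", rng),
            nn.Dense(256, 6400, "linear", rng),
            nn.Reshape((5, 5, 256)),
            nn.Conv2D(256, 128, (2, 2), "same", "relu", rng),
            nn.Conv2D(128, 64, (3, 3), "same", "relu", rng),
            nn.Conv2D(64, 1, (1, 1), "same", "linear", rng),
        ]
    )


class _CNNRegressorBase(RegressorMixin, BaseEstimator):
    """Shared fit/predict logic for the 2D and 3D patch networks."""

    _temporal = False

    def __init__(self, epochs=50, batch_size=32, learning_rate=1e-3, seed=0):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    def _build(self, rng):  # pragma: no cover - overridden
        raise NotImplementedError

    def fit(self, X, y, validation_data=None):
        X, y = _check_tiles(X, y, temporal=self._temporal)
        if validation_data is not None:
            Xv, yv = _check_tiles(*validation_data, temporal=self._temporal)
        else:
            # without a held-out fold, checkpoint on the training loss
            Xv, yv = X, y

        feat = _pixels(X)
        self.feature_mean_ = feat.mean(axis=0)
        sd = feat.std(axis=0)
        self.feature_std_ = np.where(sd > 0, sd, 1.0)
        self.y_mean_ = float(np.mean(y))
        y_sd = float(np.std(y))
        self.y_std_ = y_sd if y_sd > 0 else 1.0

        rng = np.random.default_rng(self.seed)
        self.network_ = self._build(rng)
        self.n_params_ = self.network_.n_params
        history = nn.fit(
            self.network_,
            self._transform(X),
            (y - self.y_mean_) / self.y_std_,
            self._transform(Xv),
            (yv - self.y_mean_) / self.y_std_,
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.learning_rate,
            rng=rng,
        )
        self.history_ = history
        self.best_epoch_ = history["best_epoch"]
        self.n_features_in_ = X.shape[-1]
        return self

    def _transform(self, X):
        return (X - self.feature_mean_) / self.feature_std_

    def predict(self, X):
        check_is_fitted(self, "network_")
        X = _check_tiles(X, temporal=self._temporal)
        out = self.network_.predict(self._transform(X))
        return out[..., 0].astype(np.float64) * self.y_std_ + self.y_mean_


class CNN2DRegressor(_CNNRegressorBase):
    """Single-date autoencoder-like 2D convolutional patch regressor."""

    _temporal = False

    def _build(self, rng):
        return build_cnn2d(rng)


class CNN3DRegressor(_CNNRegressorBase):
    """Five-date spatio-temporal convolutional patch regressor."""

    _temporal = True

    def _build(self, rng):
        return build_cnn3d(rng)


def save_model(model, path_stem) -> None:
    """Persist any of the five model kinds under ``path_stem`` + suffixes.

    Statistical models go to a single JSON file; boosted trees use the
    XGBoost JSON checkpoint plus a metadata sidecar; networks store their
    flat weight vector and normalizer in an .npz with a JSON spec sidecar
    and the training history as CSV.
    """
    import json
    from pathlib import Path

    path_stem = Path(path_stem)
    if isinstance(model, TileNullRegressor):
        path_stem.with_suffix(".json").write_text(
            json.dumps({"kind": "null", "mean": model.mean_})
        )
    elif isinstance(model, TileLinearRegressor):
        path_stem.with_suffix(".json").write_text(
            json.dumps(
                {
                    "kind": "linear",
                    "coef": model.coef_.tolist(),
                    "intercept": model.intercept_,
                    "aliased": list(model.aliased_),
                }
            )
        )
    elif isinstance(model, TileGradientBoostingRegressor):
        meta = {
            "kind": "xgboost",
            "base_score": model.base_score_,
            "params": model.get_params(),
        }
        path_stem.with_suffix(".json").write_text(json.dumps(meta))
        if model.booster_ is not None:
            model.booster_.save_model(str(path_stem) + ".booster.json")  # core Booster
    elif isinstance(model, _CNNRegressorBase):
        kind = "cnn3d" if isinstance(model, CNN3DRegressor) else "cnn2d"
        np.savez(
            str(path_stem) + ".weights.npz",
            flat_params=model.network_.flat_params,
            feature_mean=model.feature_mean_,
            feature_std=model.feature_std_,
            y_mean=model.y_mean_,
            y_std=model.y_std_,
        )
        path_stem.with_suffix(".json").write_text(
            json.dumps(
                {
                    "kind": kind,
                    "params": model.get_params(),
                    "best_epoch": model.best_epoch_,
                    "n_params": model.n_params_,
                }
            )
        )
        import pandas as pd

        pd.DataFrame(
            {
                "epoch": range(len(model.history_["train_loss"])),
                "train_loss": model.history_["train_loss"],
                "val_loss": model.history_["val_loss"],
            }
        ).to_csv(str(path_stem) + ".history.csv", index=False)
    else:
        raise ConfigurationError(f"cannot save model of type {type(model).__name__}")


def load_model(path_stem):
    """Inverse of :func:`save_model`."""
    import json
    from pathlib import Path

    path_stem = Path(path_stem)
    meta = json.loads(path_stem.with_suffix(".json").read_text())
    kind = meta["kind"]
    if kind == "null":
        m = TileNullRegressor()
        m.mean_ = meta["mean"]
        return m
    if kind == "linear":
        m = TileLinearRegressor()
        m.coef_ = np.asarray(meta["coef"])
        m.intercept_ = meta["intercept"]
        m.aliased_ = tuple(meta["aliased"])
        return m
    if kind == "xgboost":
        import xgboost as xgb

        m = TileGradientBoostingRegressor(**meta["params"])
        m.base_score_ = meta["base_score"]
        booster_path = str(path_stem) + ".booster.json"
        if Path(booster_path).exists():
            m.booster_ = xgb.Booster(model_file=booster_path)
        else:
            m.booster_ = None
        return m
    if kind in ("cnn2d", "cnn3d"):
        cls = CNN3DRegressor if kind == "cnn3d" else CNN2DRegressor
        m = cls(**meta["params"])
        data = np.load(str(path_stem) + ".weights.npz")
        m.network_ = m._build(np.random.default_rng(m.seed))
        m.network_.set_weights(data["flat_params"])
        m.feature_mean_ = data["feature_mean"]
        m.feature_std_ = data["feature_std"]
        m.y_mean_ = float(data["y_mean"])
        m.y_std_ = float(data["y_std"])
        m.best_epoch_ = meta["best_epoch"]
        m.n_params_ = meta["n_params"]
        return m
    raise ConfigurationError(f"unknown model kind {kind!r} in {path_stem}")


def make_model(kind: str, seed: int = 0):
    """Factory over the five model kinds used by the experiment driver."""
    if kind == "null":
        return TileNullRegressor()
    if kind == "linear":
        return TileLinearRegressor()
    if kind == "xgboost":
        return TileGradientBoostingRegressor(seed=seed)
    if kind == "cnn2d":
        return CNN2DRegressor(seed=seed)
    if kind == "cnn3d":
        return CNN3DRegressor(seed=seed)
    raise ConfigurationError(f"unknown model kind {kind!r}; known: {MODEL_KINDS}")
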