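"""Evaluation metrics, feature-blanking importance, and cross-fold summaries.

Four metrics, computed over valid pixels (Y observed, Yhat predicted, n
pixels):

* RMSE  = sqrt(mean (Y_i - Yhat_i)^2)                     [Mg/ha]
* MAE   = mean |Yhat_i - Y_i|                             [Mg/ha]
* MBE   = mean (Yhat_i - Y_i)  (positive = overprediction) [Mg/ha]
* R^2   = squared product-moment correlation between observed and
  predicted — undefined (reported as ``None``, printed "n.d.") when either
  series has zero variance, as for a constant-prediction null model.

rRMSE expresses RMSE as a percentage of the mean observed yield.

Feature importance follows the blanking protocol: replace one feature
everywhere in the test set by its test-set pixel mean (on the raw feature
scale, before any model-internal normalization), re-evaluate, and report
DeltaRMSE = blanked RMSE - original RMSE.  Larger positive values mean the
model leaned on that feature; near-zero or negative values mean it did not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .prep import TileSet
from .rasters import FEATURE_NAMES

__all__ = [
    "EvalReport",
    "ImportanceResult",
    "compute_metrics",
    "evaluate_model",
    "blank_feature",
    "feature_importance",
    "cross_fold_summary",
    "reports_to_frame",
]


@dataclass(frozen=True)
class EvalReport:
    n: int
    rmse: float
    mae: float
    mbe: float
    r2: float | None  # None = not defined (zero-variance series)
    rrmse: float  # % of mean observed yield
    fold_id: str = ""
    model_kind: str = ""
    date_label: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ImportanceResult:
    feature: str
    delta_rmse: float  # Mg/ha, blanked minus original
    delta_rrmse: float  # percentage points of mean observed yield
    fold_id: str = ""


def compute_metrics(
    observed: np.ndarray,
    predicted: np.ndarray,
    fold_id: str = "",
    model_kind: str = "",
    date_label: str = "",
) -> EvalReport:
    """Compute RMSE, MAE, MBE, R^2 and rRMSE over paired pixels."""
    observed = np.asarray(observed, dtype=np.float64).ravel()
    predicted = np.asarray(predicted, dtype=np.float64).ravel()
    if observed.shape != predicted.shape:
        raise InputError(
            f"observed ({observed.shape}) and predicted ({predicted.shape}) "
            "lengths differ"
        )
    n = observed.size
    if n == 0:
        raise InputError("no pixels to evaluate")
    err = predicted - observed
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    mbe = float(np.mean(err))
    d_obs = observed - observed.mean()
    d_pred = predicted - predicted.mean()
    ss_obs = float(np.sum(d_obs**2))
    ss_pred = float(np.sum(d_pred**2))
    # a constant series (e.g. the null model) has no defined correlation;
    # test min==max rather than ss==0 to be robust to mean round-off
    if observed.min() == observed.max() or predicted.min() == predicted.max():
        r2: float | None = None
    else:
        r2 = float(np.sum(d_obs * d_pred) ** 2 / (ss_obs * ss_pred))
    mean_obs = float(observed.mean())
    rrmse = float(100.0 * rmse / mean_obs) if mean_obs != 0 else float("nan")
    return EvalReport(n, rmse, mae, mbe, r2, rrmse, fold_id, model_kind, date_label)


def evaluate_model(model, tiles: TileSet, **labels) -> EvalReport:
    """Predict on a tile set and score against its yield patches."""
    pred = model.predict(tiles.features)
    return compute_metrics(tiles.yields, pred, **labels)


def blank_feature(tiles: TileSet, feature: str | Sequence[str]) -> TileSet:
    """Replace feature layer(s) by the pixel mean over the whole tile set.

    Blanking happens on the raw feature scale; a model's internal
    normalizer (fitted on its training fold) then sees a constant layer at
    the test-set mean.  Passing several names blanks them simultaneously
    (diagnostic mode).
    """
    names = [feature] if isinstance(feature, str) else list(feature)
    feats = tiles.features.copy()
    for name in names:
        if name not in FEATURE_NAMES:
            raise ConfigurationError(
                f"unknown feature {name!r}; known: {FEATURE_NAMES}"
            )
        idx = FEATURE_NAMES.index(name)
        feats[..., idx] = feats[..., idx].mean()
    return replace(tiles, features=feats)


def feature_importance(
    model, test_tiles: TileSet, fold_id: str = ""
) -> list[ImportanceResult]:
    """Blank each of the 7 features in turn and measure the RMSE increase."""
    base = evaluate_model(model, test_tiles)
    mean_obs = float(np.mean(test_tiles.yields))
    results = []
    for name in FEATURE_NAMES:
        blanked = evaluate_model(model, blank_feature(test_tiles, name))
        d_rmse = blanked.rmse - base.rmse
        results.append(
            ImportanceResult(
                feature=name,
                delta_rmse=d_rmse,
                delta_rrmse=100.0 * d_rmse / mean_obs,
                fold_id=fold_id,
            )
        )
    return results


def reports_to_frame(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Tabulate reports; undefined R^2 becomes NaN in the frame."""
    rows = []
    for r in reports:
        d = r.to_dict()
        if d["r2"] is None:
            d["r2"] = np.nan
        rows.append(d)
    return pd.DataFrame(rows)


def cross_fold_summary(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Per-model mean and sd of each metric across folds.

    Groups by (model kind, date label); warns when a group is missing
    folds and averages over what is present.
    """
    if not reports:
        raise InputError("no reports to summarize")
    frame = reports_to_frame(reports)
    n_folds = frame.groupby(["model_kind", "date_label"])["fold_id"].nunique()
    incomplete = n_folds[n_folds < 4]
    if len(incomplete):
        warnings.warn(
            f"summary over incomplete folds: {incomplete.to_dict()}",
            stacklevel=2,
        )
    metrics = ["rmse", "mae", "mbe", "r2", "rrmse"]
    out = frame.groupby(["model_kind", "date_label"])[metrics].agg(["mean", "std"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.reset_index()
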