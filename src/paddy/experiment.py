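"""End-to-end experiment driver.

Expands one experiment configuration into the full grid — simulated rasters,
per-date feature stacks, tiles, four spatial folds, per-date 2D-capable
models plus the five-date spatio-temporal network, evaluation reports,
prediction maps, and a cross-fold summary — under a deterministic output
tree with a manifest recording every artifact's inputs and seed.

Re-running with the same configuration skips completed stages; re-running
on a directory produced by a *different* configuration refuses with a
configuration error.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import FieldConfig
from .errors import ConfigurationError
from .evaluate import (
    cross_fold_summary,
    evaluate_model,
    feature_importance,
    reports_to_frame,
)
from .indices import build_feature_stack
from .models import make_model, save_model
from .prep import (
    FOLD_IDS,
    assemble_map,
    difference_map,
    partition_folds,
    select_tiles,
    stack_time,
    tile,
)
from .rasters import (
    write_feature_raster,
    write_reflectance_stack,
    write_yield_raster,
    read_feature_raster,
    read_yield_raster,
)
from .simulate import simulate_field

#: model kinds that train one model per acquisition date
PER_DATE_KINDS = ("null", "linear", "xgboost", "cnn2d")


@dataclass
class ExperimentConfig:
    """One experiment grid: field, model kinds, folds, dates, seed."""

    field: FieldConfig = field(default_factory=FieldConfig)
    models: tuple[str, ...] = ("null", "linear", "xgboost", "cnn2d", "cnn3d")
    folds: tuple[str, ...] = FOLD_IDS
    dates_2d: tuple[int, ...] | None = None  # date indices; None = all dates
    dates_3d: tuple[int, ...] | None = None  # exactly 5 indices; None = auto
    seed: int = 0

    def __post_init__(self) -> None:
        for f in self.folds:
            if f not in FOLD_IDS:
                raise ConfigurationError(f"unknown fold {f!r}")
        if self.dates_2d is None:
            self.dates_2d = tuple(range(self.field.n_dates))
        for d in self.dates_2d:
            if not 0 <= d < self.field.n_dates:
                raise ConfigurationError(f"date index {d} out of range")
        if "cnn3d" in self.models:
            if self.dates_3d is None:
                if self.field.n_dates < 5:
                    raise ConfigurationError(
                        "the spatio-temporal model needs 5 dates; "
                        f"field has {self.field.n_dates}"
                    )
                self.dates_3d = tuple(range(self.field.n_dates - 5, self.field.n_dates))
            if len(self.dates_3d) != 5:
                raise ConfigurationError(
                    f"dates_3d must list exactly 5 dates, got {self.dates_3d}"
                )

    def to_dict(self) -> dict:
        return {
            "field": self.field.to_dict(),
            "models": list(self.models),
            "folds": list(self.folds),
            "dates_2d": list(self.dates_2d),
            "dates_3d": list(self.dates_3d) if self.dates_3d else None,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if isinstance(d.get("field"), dict):
            d["field"] = FieldConfig.from_dict(d["field"])
        for key in ("models", "folds", "dates_2d", "dates_3d"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def derive_seed(base: int, *labels) -> int:
    """Stable per-task seed below 2**31, derived from the run seed."""
    tag = "|".join(str(x) for x in labels)
    return (base * 2654435761 + zlib.crc32(tag.encode())) % (2**31)


class Manifest:
    """JSON record of every produced artifact and its provenance."""

    def __init__(self, path: Path, config_hash: str):
        self.path = path
        if path.exists():
            self.data = json.loads(path.read_text())
            if self.data.get("config_hash") != config_hash:
                raise ConfigurationError(
                    f"output directory holds results for a different "
                    f"configuration (manifest hash {self.data.get('config_hash')}, "
                    f"requested {config_hash}); use a fresh directory"
                )
        else:
            self.data = {
                "config_hash": config_hash,
                "version": __version__,
                "artifacts": {},
            }

    def done(self, key: str) -> bool:
        entry = self.data["artifacts"].get(key)
        return bool(entry) and all(
            (self.path.parent / p).exists() for p in entry["paths"]
        )

    def record(self, key: str, paths: list[Path], **meta) -> None:
        self.data["artifacts"][key] = {
            "paths": [str(p.relative_to(self.path.parent)) for p in paths],
            **meta,
        }
        self.save()

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict:
    """Run (or resume) the full grid; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    (out / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True)
    )
    manifest = Manifest(out / "manifest.json", chash)

    # --- stage 1: simulate rasters -------------------------------------
    raster_dir = out / "rasters"
    stack_paths = [
        raster_dir / f"reflectance_{i:02d}.tif" for i in range(config.field.n_dates)
    ]
    yield_path = raster_dir / "yield.tif"
    if not manifest.done("simulate"):
        raster_dir.mkdir(exist_ok=True)
        stacks, yr, _ = simulate_field(config.field)
        for p, stack in zip(stack_paths, stacks):
            write_reflectance_stack(
                p, stack, config=config.field.to_dict(), seed=config.field.seed
            )
        write_yield_raster(
            yield_path, yr, config=config.field.to_dict(), seed=config.field.seed
        )
        manifest.record(
            "simulate",
            stack_paths + [yield_path],
            seed=config.field.seed,
            stage="simulate",
        )

    # --- stage 2: vegetation-index features ----------------------------
    feat_dir = out / "features"
    feat_paths = [
        feat_dir / f"features_{i:02d}.tif" for i in range(config.field.n_dates)
    ]
    if not manifest.done("indices"):
        feat_dir.mkdir(exist_ok=True)
        from .rasters import read_reflectance_stack

        for sp, fp in zip(stack_paths, feat_paths):
            write_feature_raster(fp, build_feature_stack(read_reflectance_stack(sp)))
        manifest.record(
            "indices", feat_paths, inputs=[str(p) for p in stack_paths],
            stage="indices",
        )

    # --- stage 3: tiles + folds ----------------------------------------
    yr = read_yield_raster(yield_path)
    tile_sets = [read_and_tile(fp, yr) for fp in feat_paths]
    folds = {f.fold_id: f for f in partition_folds(tile_sets[0])}
    fold_path = out / "folds.json"
    if not manifest.done("folds"):
        fold_path.write_text(
            json.dumps(
                {fid: f.role_grid.tolist() for fid, f in folds.items()},
                sort_keys=True,
            )
        )
        manifest.record("folds", [fold_path], stage="prepare")

    temporal = None
    if "cnn3d" in config.models:
        temporal = stack_time([tile_sets[d] for d in config.dates_3d])

    # --- stage 4: train + evaluate -------------------------------------
    model_dir = out / "models"
    report_dir = out / "reports"
    map_dir = out / "maps"
    for d in (model_dir, report_dir, map_dir):
        d.mkdir(exist_ok=True)
    reports = []
    stage_of = {i: s for i, s in enumerate(config.field.stage_labels)}

    tasks = []
    for kind in config.models:
        if kind in PER_DATE_KINDS:
            tasks += [(kind, fid, d) for fid in config.folds for d in config.dates_2d]
        elif kind == "cnn3d":
            tasks += [(kind, fid, None) for fid in config.folds]
        else:
            raise ConfigurationError(f"unknown model kind {kind!r}")

    for kind, fid, date_idx in tasks:
        date_tag = "alldates" if date_idx is None else f"date{date_idx:02d}"
        key = f"train/{kind}/{fid}/{date_tag}"
        report_path = report_dir / f"{kind}_{fid}_{date_tag}.json"
        if manifest.done(key):
            reports.append(_load_report(report_path))
            continue
        tiles = temporal if date_idx is None else tile_sets[date_idx]
        fold = folds[fid]
        train = select_tiles(tiles, fold, "train")
        val = select_tiles(tiles, fold, "validation")
        test = select_tiles(tiles, fold, "test")
        seed = derive_seed(config.seed, kind, fid, date_tag)
        model = make_model(kind, seed=seed)
        if kind in ("cnn2d", "cnn3d"):
            model.fit(train.features, train.yields,
                      validation_data=(val.features, val.yields))
        else:
            # statistical models treat train and validation equivalently
            merged = _merge(train, val)
            model.fit(merged.features, merged.yields)
        date_label = "+".join(
            stage_of[d] for d in (config.dates_3d if date_idx is None else [date_idx])
        )
        report = evaluate_model(
            model, test, fold_id=fid, model_kind=kind, date_label=date_label
        )
        _save_report(report_path, report)
        model_path = model_dir / f"{kind}_{fid}_{date_tag}"
        save_model(model, model_path)
        # field-scale prediction + difference maps on the full tile set
        pred_map = assemble_map(tiles, model.predict(tiles.features))
        obs_map = assemble_map(tiles, tiles.yields)
        map_path = map_dir / f"{kind}_{fid}_{date_tag}_predicted.tif"
        diff_path = map_dir / f"{kind}_{fid}_{date_tag}_difference.tif"
        write_yield_raster(map_path, pred_map, model=kind, fold=fid)
        write_yield_raster(diff_path, difference_map(obs_map, pred_map), model=kind, fold=fid)
        manifest.record(
            key,
            [report_path, map_path, diff_path],
            seed=seed,
            model=kind,
            fold=fid,
            date=date_tag,
            stage="train",
        )
        reports.append(report)

    # --- stage 5: cross-fold summary -----------------------------------
    summary_path = out / "summary.csv"
    reports_path = out / "reports.csv"
    if not manifest.done("summary"):
        frame = reports_to_frame(reports)
        frame.to_csv(reports_path, index=False)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cross_fold_summary(reports).to_csv(summary_path, index=False)
        manifest.record("summary", [summary_path, reports_path], stage="evaluate")
    return manifest.data


def read_and_tile(feature_path: Path, yield_raster):
    return tile(read_feature_raster(feature_path), yield_raster)


def _merge(a, b):
    import numpy as np
    from dataclasses import replace

    return replace(
        a,
        features=np.concatenate([a.features, b.features]),
        yields=np.concatenate([a.yields, b.yields]),
        rows=np.concatenate([a.rows, b.rows]),
        cols=np.concatenate([a.cols, b.cols]),
    )


def _save_report(path: Path, report) -> None:
    path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))


def _load_report(path: Path):
    from .evaluate import EvalReport

    return EvalReport(**json.loads(path.read_text()))


def run_importance(config: ExperimentConfig, out_dir: str | Path,
                   kind: str = "cnn2d", date_idx: int | None = None) -> pd.DataFrame:
    """Feature-blanking importance for every fold of one trained model kind.

    Requires a completed :func:`run_experiment` directory; loads each
    fold's trained model, blanks each feature over that fold's test tiles,
    and tabulates the RMSE increase.
    """
    from .models import load_model

    out = Path(out_dir)
    manifest = Manifest(out / "manifest.json", config.config_hash())
    if date_idx is None:
        date_idx = config.dates_2d[-1]
    date_tag = f"date{date_idx:02d}"
    yr = read_yield_raster(out / "rasters" / "yield.tif")
    tiles = read_and_tile(out / "features" / f"features_{date_idx:02d}.tif", yr)
    folds = {f.fold_id: f for f in partition_folds(tiles)}
    rows = []
    for fid in config.folds:
        key = f"train/{kind}/{fid}/{date_tag}"
        if not manifest.done(key):
            raise ConfigurationError(f"no trained model for {key}; run the grid first")
        model = load_model(out / "models" / f"{kind}_{fid}_{date_tag}")
        test = select_tiles(tiles, folds[fid], "test")
        for res in feature_importance(model, test, fold_id=fid):
            rows.append(
                {
                    "model_kind": kind,
                    "fold_id": fid,
                    "feature": res.feature,
                    "delta_rmse": res.delta_rmse,
                    "delta_rrmse": res.delta_rrmse,
                }
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(out / f"importance_{kind}_{date_tag}.csv", index=False)
    return frame
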