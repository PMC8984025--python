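"""Downsampling, tiling, temporal stacking, and spatial fold partitioning.

The working unit of the analysis is the non-overlapping 5x5-pixel tile
(2.5 m x 2.5 m at 50 cm resolution).  Tiles are addressed by 0-based
row-major tile-grid coordinates; tile (i, j) covers pixel rows
[5i, 5i+5) and cols [5j, 5j+5), half-open.  A tile is retained only if
every feature, date, and yield cell inside it is valid.

Cross-validation is spatial: the tile grid is cut into a 4x4 lattice of
rectangular blocks and whole blocks are assigned to train / validation /
test roles (~50/25/25) by a fixed per-fold template, so test regions are
contiguous areas of the field never seen during training.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, InputError
from .rasters import FEATURE_NAMES, FeatureRaster, YieldRaster

__all__ = [
    "aggregate",
    "TileSet",
    "tile",
    "stack_time",
    "FoldSpec",
    "partition_folds",
    "select_tiles",
    "assemble_map",
    "difference_map",
]

ROLES = ("train", "validation", "test")
FOLD_IDS = ("A", "B", "C", "D")


def aggregate(
    values: np.ndarray, factor: int, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Block-mean downsampling by an integer factor.

    Each output cell is the mean of the valid cells in its ``factor x
    factor`` block; it is invalid only if the whole block is.  Trailing
    partial blocks are dropped (field edges are cropped anyway).
    Returns ``(values, mask)``.
    """
    if not float(factor).is_integer() or factor < 1:
        raise ConfigurationError(f"aggregation factor must be integer >= 1, got {factor}")
    factor = int(factor)
    values = np.asarray(values, dtype=np.float64)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    h, w = values.shape
    if h < factor or w < factor:
        raise InputError(f"raster {values.shape} smaller than factor {factor}")
    h2, w2 = h // factor, w // factor
    v = values[: h2 * factor, : w2 * factor].reshape(h2, factor, w2, factor)
    m = mask[: h2 * factor, : w2 * factor].reshape(h2, factor, w2, factor)
    counts = m.sum(axis=(1, 3))
    sums = np.where(m, v, 0.0).sum(axis=(1, 3))
    out_mask = counts > 0
    out = np.zeros((h2, w2))
    np.divide(sums, counts, out=out, where=out_mask)
    return out, out_mask


@dataclass
class TileSet:
    """Retained 5x5 tiles of a (possibly multi-date) feature + yield stack.

    features : (n, s, s, 7) single date, or (n, s, s, D, 7) temporal
    yields   : (n, s, s) Mg/ha
    rows, cols : (n,) tile-grid coordinates of each retained tile
    grid_shape : (tile_rows, tile_cols) of the full tile grid
    field_shape : pixel shape of the source rasters
    """

    features: np.ndarray
    yields: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    grid_shape: tuple[int, int]
    field_shape: tuple[int, int]
    tile_size: int = 5
    date_labels: tuple[str, ...] = ("",)

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        if not (len(self.features) == len(self.yields) == len(self.rows) == len(self.cols)):
            raise InputError("tile arrays have inconsistent lengths")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def is_temporal(self) -> bool:
        return self.features.ndim == 5

    @property
    def n_dates(self) -> int:
        return self.features.shape[3] if self.is_temporal else 1

    def retained_grid(self) -> np.ndarray:
        """Boolean tile-grid map of retained tiles."""
        g = np.zeros(self.grid_shape, dtype=bool)
        g[self.rows, self.cols] = True
        return g

    def subset(self, index: np.ndarray) -> "TileSet":
        return replace(
            self,
            features=self.features[index],
            yields=self.yields[index],
            rows=self.rows[index],
            cols=self.cols[index],
        )


def tile(
    feature_raster: FeatureRaster, yield_raster: YieldRaster, size: int = 5
) -> TileSet:
    """Split co-registered feature and yield rasters into complete tiles.

    Feature and yield masks are intersected (co-masking); a tile is retained
    only if all ``size*size`` pixels are valid in the combined mask.
    Trailing rows/cols that do not fill a tile are never tiled.
    """
    if feature_raster.shape != yield_raster.shape:
        raise InputError(
            f"feature raster {feature_raster.shape} and yield raster "
            f"{yield_raster.shape} are not co-registered"
        )
    h, w = feature_raster.shape
    tr, tc = h // size, w // size
    if tr == 0 or tc == 0:
        raise InputError(f"raster {feature_raster.shape} too small for {size}x{size} tiles")
    mask = feature_raster.mask & yield_raster.mask
    mask_t = mask[: tr * size, : tc * size].reshape(tr, size, tc, size)
    complete = mask_t.all(axis=(1, 3))
    rows, cols = np.nonzero(complete)

    # (H, W, 7) pixel-major view for easy patch extraction
    feats_hw = np.moveaxis(feature_raster.data, 0, -1)
    feats = np.empty((len(rows), size, size, len(FEATURE_NAMES)))
    ys = np.empty((len(rows), size, size))
    for k, (i, j) in enumerate(zip(rows, cols)):
        feats[k] = feats_hw[i * size : (i + 1) * size, j * size : (j + 1) * size]
        ys[k] = yield_raster.values[i * size : (i + 1) * size, j * size : (j + 1) * size]
    return TileSet(
        features=feats,
        yields=ys,
        rows=rows,
        cols=cols,
        grid_shape=(tr, tc),
        field_shape=(h, w),
        tile_size=size,
        date_labels=(feature_raster.date_label,),
    )


def stack_time(tile_sets: list[TileSet]) -> TileSet:
    """Stack single-date tile sets along a date axis (ordered by date).

    A tile is retained only if complete at every date; features become
    (n, s, s, n_dates, 7).
    """
    if not tile_sets:
        raise InputError("no tile sets to stack")
    first = tile_sets[0]
    for ts in tile_sets[1:]:
        if ts.grid_shape != first.grid_shape or ts.tile_size != first.tile_size:
            raise InputError("tile sets have mismatched tile grids")
        if ts.is_temporal:
            raise InputError("stack_time expects single-date tile sets")
    common = first.retained_grid()
    for ts in tile_sets[1:]:
        common &= ts.retained_grid()
    rows, cols = np.nonzero(common)
    key = {(i, j): k for k, (i, j) in enumerate(zip(rows, cols))}

    n = len(rows)
    s = first.tile_size
    feats = np.empty((n, s, s, len(tile_sets), len(FEATURE_NAMES)))
    ys = np.empty((n, s, s))
    for d, ts in enumerate(tile_sets):
        for k, (i, j) in enumerate(zip(ts.rows, ts.cols)):
            idx = key.get((int(i), int(j)))
            if idx is not None:
                feats[idx, :, :, d, :] = ts.features[k]
                if d == 0:
                    ys[idx] = ts.yields[k]
    # yields must come from a date that retained the tile; date 0 does by construction
    return TileSet(
        features=feats,
        yields=ys,
        rows=rows,
        cols=cols,
        grid_shape=first.grid_shape,
        field_shape=first.field_shape,
        tile_size=s,
        date_labels=tuple(ts.date_labels[0] for ts in tile_sets),
    )


@dataclass
class FoldSpec:
    """Role assignment of every tile-grid coordinate for one fold."""

    fold_id: str
    role_grid: np.ndarray  # (tile_rows, tile_cols) of {train,validation,test,excluded}

    def role_counts(self) -> dict[str, int]:
        return {r: int((self.role_grid == r).sum()) for r in ROLES}

    def fractions(self) -> dict[str, float]:
        counts = self.role_counts()
        total = sum(counts.values())
        return {r: c / total for r, c in counts.items()} if total else {}


# Per-fold assignment of the 4 block-strips (each strip = 4 of the 16 blocks).
# Across the four folds every strip serves as test exactly once.
_FOLD_TEMPLATES = {
    "A": {"test": 0, "validation": 1},
    "B": {"test": 1, "validation": 2},
    "C": {"test": 2, "validation": 3},
    "D": {"test": 3, "validation": 0},
}


def partition_folds(tile_set: TileSet, scheme: str = "lattice4") -> list[FoldSpec]:
    """Partition retained tiles into four spatial train/val/test folds.

    The tile grid is cut into a 4x4 lattice of rectangular blocks whose
    horizontal strip boundaries balance the *retained* tile counts (so an
    edge buffer does not skew the split).  In each fold one strip of 4
    blocks is the test region, another is validation, and the remaining 8
    blocks train (50/25/25).  The scheme is deterministic; across folds
    A-D every strip is the test region exactly once.
    """
    if scheme != "lattice4":
        raise ConfigurationError(f"unknown fold scheme {scheme!r}")
    tr, tc = tile_set.grid_shape
    if tr < 4 or tc < 4:
        raise ConfigurationError(
            f"tile grid {tile_set.grid_shape} too small for a 4x4 block lattice"
        )
    retained = tile_set.retained_grid()
    if not retained.any():
        raise ConfigurationError("no retained tiles to partition")
    # strip boundaries at the quartiles of the cumulative retained count
    cum = np.cumsum(retained.sum(axis=1))
    total = cum[-1]
    quartiles = total * np.arange(1, 4) / 4.0
    bounds = np.searchsorted(cum, quartiles, side="left") + 1
    strip_of_row = np.searchsorted(bounds, np.arange(tr), side="right")
    folds = []
    for fold_id in FOLD_IDS:
        template = _FOLD_TEMPLATES[fold_id]
        role_grid = np.full(tile_set.grid_shape, "train", dtype="<U10")
        role_grid[strip_of_row == template["test"], :] = "test"
        role_grid[strip_of_row == template["validation"], :] = "validation"
        role_grid[~retained] = "excluded"
        folds.append(FoldSpec(fold_id=fold_id, role_grid=role_grid))
    return folds


def select_tiles(tile_set: TileSet, fold: FoldSpec, role: str) -> TileSet:
    """Subset of the tiles assigned the given role in the given fold."""
    if role not in ROLES:
        raise ConfigurationError(f"unknown role {role!r}")
    roles = fold.role_grid[tile_set.rows, tile_set.cols]
    return tile_set.subset(roles == role)


def assemble_map(tile_set: TileSet, predictions: np.ndarray) -> YieldRaster:
    """Reassemble per-tile prediction patches into a field-scale raster.

    ``predictions`` is (n, s, s), aligned with the tile set; pixels of
    excluded tiles (and trailing remainders) are nodata.  With
    ``predictions = tile_set.yields`` this inverts :func:`tile` on the
    retained extents exactly.
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    if predictions.shape != tile_set.yields.shape:
        raise InputError(
            f"predictions {predictions.shape} do not match the "
            f"{tile_set.yields.shape} retained tiles"
        )
    s = tile_set.tile_size
    values = np.zeros(tile_set.field_shape)
    mask = np.zeros(tile_set.field_shape, dtype=bool)
    for k, (i, j) in enumerate(zip(tile_set.rows, tile_set.cols)):
        values[i * s : (i + 1) * s, j * s : (j + 1) * s] = predictions[k]
        mask[i * s : (i + 1) * s, j * s : (j + 1) * s] = True
    return YieldRaster(values, mask)


def difference_map(observed: YieldRaster, predicted: YieldRaster) -> YieldRaster:
    """Prediction-error map: observed minus predicted, on the common mask."""
    if observed.shape != predicted.shape:
        raise InputError("observed/predicted shape mismatch")
    mask = observed.mask & predicted.mask
    return YieldRaster(np.where(mask, observed.values - predicted.values, 0.0), mask)
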