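"""Raster containers and TIFF input/output.

Rasters are plain float32 numpy grids with an explicit boolean validity mask.
On disk: multiband TIFF (one band per layer) with nodata cells filled with
``NODATA``; a JSON sidecar records layer names, nodata value, grid resolution
and, for simulated data, the generating config and seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import InputError

NODATA = -9999.0

BAND_NAMES = ("blue", "green", "red", "red_edge", "nir")

#: Canonical feature order: the six vegetation indices alphabetically, then
#: the thermal layer.  Models depend on this being fixed.
FEATURE_NAMES = ("CIgreen", "GNDVI", "NAVI", "NDVI", "RENDVI", "TGI", "thermal")


def _check_shapes(arrays: dict[str, np.ndarray]) -> tuple[int, int]:
    shapes = {name: a.shape for name, a in arrays.items()}
    if len(set(shapes.values())) != 1:
        raise InputError(f"layer shapes differ: {shapes}")
    return next(iter(shapes.values()))


@dataclass
class YieldRaster:
    """Observed or predicted rough-rice yield (Mg/ha) on the 50 cm grid."""

    values: np.ndarray
    mask: np.ndarray  # True where valid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        _check_shapes({"values": self.values, "mask": self.mask})

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class ReflectanceStack:
    """Co-registered reflectance bands plus thermal for one acquisition date.

    Reflectances are unitless in [0, 1]; thermal is degrees Celsius.  Values
    outside [0, 1] in a reflectance band are flagged with a warning (sensor
    calibration can overshoot) but not rejected.
    """

    bands: dict[str, np.ndarray]  # keys = BAND_NAMES
    thermal: np.ndarray | None  # None models a thermal-sensor malfunction
    mask: np.ndarray
    date_label: str = ""
    stage: str = ""

    def __post_init__(self) -> None:
        missing = [b for b in BAND_NAMES if b not in self.bands]
        if missing:
            raise InputError(f"missing reflectance band(s): {missing}")
        self.bands = {
            b: np.asarray(self.bands[b], dtype=np.float64) for b in BAND_NAMES
        }
        self.mask = np.asarray(self.mask, dtype=bool)
        layers = {**self.bands, "mask": self.mask}
        if self.thermal is not None:
            self.thermal = np.asarray(self.thermal, dtype=np.float64)
            layers["thermal"] = self.thermal
        _check_shapes(layers)
        for name in BAND_NAMES:
            vals = self.bands[name][self.mask]
            if vals.size and ((vals < 0) | (vals > 1)).any():
                warnings.warn(
                    f"band {name!r} has reflectance values outside [0, 1]",
                    stacklevel=2,
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def band(self, name: str) -> np.ndarray:
        if name == "thermal":
            if self.thermal is None:
                raise InputError("stack has no 'thermal' layer")
            return self.thermal
        if name not in self.bands:
            raise InputError(f"unknown band {name!r}")
        return self.bands[name]


@dataclass
class FeatureRaster:
    """The 7-layer model-input stack: six vegetation indices plus thermal."""

    data: np.ndarray  # (7, H, W) in FEATURE_NAMES order
    mask: np.ndarray
    date_label: str = ""
    stage: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3 or self.data.shape[0] != len(FEATURE_NAMES):
            raise InputError(
                f"feature data must be ({len(FEATURE_NAMES)}, H, W), "
                f"got {self.data.shape}"
            )
        if self.data.shape[1:] != self.mask.shape:
            raise InputError("feature/mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def layer(self, name: str) -> np.ndarray:
        try:
            idx = FEATURE_NAMES.index(name)
        except ValueError:
            raise InputError(f"unknown feature {name!r}") from None
        return self.data[idx]


# ---------------------------------------------------------------------------
# TIFF + JSON sidecar I/O


def write_raster(
    path: str | Path,
    layers: np.ndarray,
    mask: np.ndarray,
    layer_names: list[str],
    metadata: dict | None = None,
) -> None:
    """Write a (L, H, W) stack as float32 multiband TIFF + JSON sidecar."""
    path = Path(path)
    layers = np.asarray(layers, dtype=np.float32)
    if layers.ndim == 2:
        layers = layers[None]
    filled = np.where(mask[None], layers, np.float32(NODATA))
    tifffile.imwrite(path, filled)
    sidecar = {
        "layers": list(layer_names),
        "nodata": NODATA,
        "cell_size_m": 0.5,
        **(metadata or {}),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def read_raster(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a multiband TIFF; returns (layers, valid-mask, sidecar dict)."""
    path = Path(path)
    layers = np.asarray(tifffile.imread(path), dtype=np.float64)
    if layers.ndim == 2:
        layers = layers[None]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    nodata = meta.get("nodata", NODATA)
    mask = ~np.any(layers == nodata, axis=0)
    layers = np.where(mask[None], layers, np.nan)
    return layers, mask, meta


def write_feature_raster(path: str | Path, fr: FeatureRaster, **metadata) -> None:
    write_raster(
        path,
        fr.data,
        fr.mask,
        list(FEATURE_NAMES),
        {"date_label": fr.date_label, "stage": fr.stage, **metadata},
    )


def read_feature_raster(path: str | Path) -> FeatureRaster:
    layers, mask, meta = read_raster(path)
    if layers.shape[0] != len(FEATURE_NAMES):
        raise InputError(
            f"expected {len(FEATURE_NAMES)} feature layers, got {layers.shape[0]}"
        )
    layers = np.where(mask[None], layers, 0.0)
    return FeatureRaster(
        layers, mask, meta.get("date_label", ""), meta.get("stage", "")
    )


def write_yield_raster(path: str | Path, yr: YieldRaster, **metadata) -> None:
    write_raster(path, yr.values, yr.mask, ["yield"], metadata)


def read_yield_raster(path: str | Path) -> YieldRaster:
    layers, mask, _ = read_raster(path)
    values = np.where(mask, layers[0], 0.0)
    return YieldRaster(values, mask)


def write_reflectance_stack(
    path: str | Path, stack: ReflectanceStack, **metadata
) -> None:
    layers = np.stack([stack.bands[b] for b in BAND_NAMES] + [stack.thermal])
    write_raster(
        path,
        layers,
        stack.mask,
        list(BAND_NAMES) + ["thermal"],
        {"date_label": stack.date_label, "stage": stack.stage, **metadata},
    )


def read_reflectance_stack(path: str | Path) -> ReflectanceStack:
    layers, mask, meta = read_raster(path)
    names = meta.get("layers", list(BAND_NAMES) + ["thermal"])
    if "thermal" not in names:
        raise InputError("reflectance stack on disk lacks a 'thermal' layer")
    layers = np.where(mask[None], layers, 0.0)
    by_name = dict(zip(names, layers))
    return ReflectanceStack(
        bands={b: by_name[b] for b in BAND_NAMES if b in by_name},
        thermal=by_name["thermal"],
        mask=mask,
        date_label=meta.get("date_label", ""),
        stage=meta.get("stage", ""),
    )
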