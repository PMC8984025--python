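"""Vegetation indices and assembly of the 7-layer feature stack.

Six standard indices computed from the five reflectance bands:

=========  ==========================================================
NDVI       (rho_NIR - rho_r) / (rho_NIR + rho_r)
CIgreen    rho_NIR / rho_g - 1
RENDVI     (rho_NIR - rho_RE) / (rho_NIR + rho_RE)
GNDVI      (rho_NIR - rho_g) / (rho_NIR + rho_g)
NAVI       1 - rho_r / rho_NIR
TGI        -0.5 * [(670-480)(rho_r - rho_g) - (670-550)(rho_r - rho_b)]
=========  ==========================================================

TGI embeds the band center wavelengths (nm) of the red/green/blue channels
as constants.  Cells whose denominator vanishes (band sums for the
normalized-difference indices, rho_g for CIgreen, rho_NIR for NAVI) are
masked invalid rather than clipped; downstream tiling drops incomplete
tiles anyway.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError, ConfigurationError
from .rasters import FEATURE_NAMES, FeatureRaster, ReflectanceStack

__all__ = ["INDEX_NAMES", "compute_index", "build_feature_stack"]

INDEX_NAMES = ("CIgreen", "GNDVI", "NAVI", "NDVI", "RENDVI", "TGI")

# TGI wavelength constants (nm): red 670, green 550, blue 480.
_TGI_RG = 670.0 - 480.0
_TGI_RB = 670.0 - 550.0


def _normalized_difference(a: np.ndarray, b: np.ndarray):
    denom = a + b
    ok = denom != 0
    out = np.zeros_like(a)
    np.divide(a - b, denom, out=out, where=ok)
    return out, ok


def _ratio_minus_one(num: np.ndarray, denom: np.ndarray):
    ok = denom != 0
    out = np.zeros_like(num)
    np.divide(num, denom, out=out, where=ok)
    return out - 1.0, ok


def compute_index(name: str, stack: ReflectanceStack) -> tuple[np.ndarray, np.ndarray]:
    """Compute one index; returns ``(raster, validity_mask)``.

    The validity mask combines the stack mask with the per-index
    zero-denominator mask.
    """
    if name not in INDEX_NAMES:
        raise ConfigurationError(
            f"unknown index {name!r}; known: {sorted(INDEX_NAMES)}"
        )
    nir = stack.band("nir")
    red = stack.band("red")
    green = stack.band("green")
    blue = stack.band("blue")
    red_edge = stack.band("red_edge")

    if name == "NDVI":
        out, ok = _normalized_difference(nir, red)
    elif name == "GNDVI":
        out, ok = _normalized_difference(nir, green)
    elif name == "RENDVI":
        out, ok = _normalized_difference(nir, red_edge)
    elif name == "CIgreen":
        out, ok = _ratio_minus_one(nir, green)
    elif name == "NAVI":
        ok = nir != 0
        ratio = np.zeros_like(nir)
        np.divide(red, nir, out=ratio, where=ok)
        out = 1.0 - ratio
        out[~ok] = 0.0
    else:  # TGI — pure polynomial, always defined
        out = -0.5 * (_TGI_RG * (red - green) - _TGI_RB * (red - blue))
        ok = np.ones_like(out, dtype=bool)
    return out, ok & stack.mask


def build_feature_stack(stack: ReflectanceStack) -> FeatureRaster:
    """Assemble the canonical 7-layer feature raster from one acquisition.

    Layer order is fixed (:data:`paddy.rasters.FEATURE_NAMES`): the six
    indices alphabetically, then thermal.  The output mask is the
    intersection of the stack mask and every per-index validity mask.
    """
    if stack.thermal is None:
        raise InputError("reflectance stack is missing the 'thermal' layer")
    layers = np.empty((len(FEATURE_NAMES),) + stack.shape)
    mask = stack.mask.copy()
    for i, name in enumerate(FEATURE_NAMES):
        if name == "thermal":
            layers[i] = stack.thermal
        else:
            layers[i], ok = compute_index(name, stack)
            mask &= ok
    layers[:, ~mask] = 0.0
    return FeatureRaster(layers, mask, stack.date_label, stack.stage)
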