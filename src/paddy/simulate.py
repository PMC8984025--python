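"""Synthetic rice-field generator.

Emulates the statistical structure a UAV yield-prediction pipeline sees in a
production paddy field:

* a latent "vigor" surface — a stationary Gaussian random field standing in
  for spatial variation in nutrient and water availability — synthesized
  spectrally (circulant embedding via FFT) with squared-exponential
  covariance rho(d) = exp(-(d/l)^2), so the autocorrelation at lag l is e^-1;
* a yield map that is affine in vigor (default 9.06 +/- 0.9 Mg/ha), plus an
  optional curvilinear harvester-track artifact emulating combine label
  noise, clipped at 0 and masked within an edge buffer;
* per-date reflectance bands that are monotone (logistic) functions of vigor
  with a growth-stage-dependent gain — zero before emergence, maximal at
  booting/flowering, attenuated during grain fill — plus i.i.d. sensor
  noise.  NIR increases with vigor, red decreases, and canopy temperature
  decreases (evaporative cooling of well-watered, transpiring plants).

All randomness flows from a single :class:`numpy.random.Generator`; identical
seeds give bit-identical fields.
"""

from __future__ import annotations

import numpy as np

from .config import STAGE_GAINS, FieldConfig
from .errors import ConfigurationError
from .rasters import ReflectanceStack, YieldRaster

__all__ = [
    "simulate_latent",
    "simulate_yield",
    "simulate_reflectance",
    "simulate_field",
    "BAND_LINKS",
]

#: (baseline reflectance, vigor slope on the log-odds scale) per band.
#: Baselines are typical mid-season canopy reflectances; signs encode the
#: physics: vigorous canopy absorbs red/blue/green (chlorophyll) and
#: scatters strongly in NIR/red-edge (leaf mesophyll structure).
BAND_LINKS: dict[str, tuple[float, float]] = {
    "blue": (0.04, -0.05),
    "green": (0.08, -0.15),
    "red": (0.06, -0.50),
    "red_edge": (0.25, 0.25),
    "nir": (0.45, 0.60),
}

#: Thermal link: canopy temperature (deg C) = THERMAL_BASE - gain * slope * vigor.
THERMAL_BASE = 28.0
THERMAL_SLOPE = 3.0
#: Thermal sensor noise expressed relative to reflectance noise (deg C per
#: reflectance unit): 0.01 reflectance noise ~ 0.5 deg C radiometric noise.
THERMAL_NOISE_SCALE = 50.0


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_latent(
    config: FieldConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Sample the latent vigor field: zero mean, unit variance, stationary.

    Spectral synthesis on the torus: the circulant covariance kernel
    ``exp(-(d_wrap / l)^2)`` is diagonalized by the 2-D DFT, so coloring
    white noise with the square root of its eigenvalue field yields an
    exact stationary draw in O(N log N).
    """
    if config.height_px <= 0 or config.width_px <= 0:
        raise ConfigurationError("grid dimensions must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.height_px, config.width_px
    ell = config.correlation_length_cells

    dr = np.minimum(np.arange(h), h - np.arange(h))
    dc = np.minimum(np.arange(w), w - np.arange(w))
    d2 = dr[:, None] ** 2 + dc[None, :] ** 2
    kernel = np.exp(-d2 / ell**2)

    lam = np.fft.fft2(kernel).real
    lam = np.clip(lam, 0.0, None)  # tiny negative eigenvalues are FFT noise
    white = rng.standard_normal((h, w))
    field = np.fft.ifft2(np.sqrt(lam) * np.fft.fft2(white)).real
    return field


def harvester_tracks(shape: tuple[int, int], amplitude: float, spacing: float) -> np.ndarray:
    """Curvilinear additive label-noise pattern (Mg/ha).

    Concentric rings about the field center with a gentle angular wobble,
    emulating the circular driving pattern of a combine harvester; ring
    period equals ``spacing`` cells (the header width).
    """
    if amplitude == 0:
        return np.zeros(shape)
    h, w = shape
    r = np.arange(h)[:, None] - (h - 1) / 2.0
    c = np.arange(w)[None, :] - (w - 1) / 2.0
    rho = np.hypot(r, c)
    theta = np.arctan2(r, c)
    rho_eff = rho + 0.2 * spacing * np.sin(3.0 * theta)
    return amplitude * np.sin(2.0 * np.pi * rho_eff / spacing)


def buffer_mask(shape: tuple[int, int], buffer_cells: int) -> np.ndarray:
    """Validity mask that excludes cells within ``buffer_cells`` of any edge."""
    mask = np.zeros(shape, dtype=bool)
    b = buffer_cells
    if shape[0] > 2 * b and shape[1] > 2 * b:
        mask[b : shape[0] - b, b : shape[1] - b] = True
    return mask


def simulate_yield(latent: np.ndarray, config: FieldConfig) -> YieldRaster:
    """Map latent vigor to a yield raster with label noise and edge buffer."""
    values = config.yield_mean + config.yield_sd * latent
    values = values + harvester_tracks(
        latent.shape, config.label_noise.amplitude, config.label_noise.spacing
    )
    values = np.clip(values, 0.0, None)
    mask = buffer_mask(latent.shape, config.buffer_cells)
    return YieldRaster(values, mask)


def simulate_reflectance(
    latent: np.ndarray,
    stage: str,
    config: FieldConfig,
    rng: np.random.Generator | None = None,
    date_label: str = "",
) -> ReflectanceStack:
    """Render one acquisition date: five reflectance bands plus thermal.

    Band b at stage s: ``sigmoid(logit(base_b) + gain_s * slope_b * vigor)``
    plus N(0, sensor_noise_sd) i.i.d. noise, clipped into [0, 1]; thermal in
    deg C decreases with vigor.
    """
    if stage not in STAGE_GAINS:
        raise ConfigurationError(
            f"unknown growth stage {stage!r}; known: {sorted(STAGE_GAINS)}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gain = STAGE_GAINS[stage]
    noise_sd = config.sensor_noise_sd

    bands = {}
    for name, (base, slope) in BAND_LINKS.items():
        clean = _sigmoid(_logit(base) + gain * slope * latent)
        if noise_sd > 0:
            clean = clean + noise_sd * rng.standard_normal(latent.shape)
        bands[name] = np.clip(clean, 0.0, 1.0)

    thermal = THERMAL_BASE - THERMAL_SLOPE * gain * latent
    if noise_sd > 0:
        thermal = thermal + THERMAL_NOISE_SCALE * noise_sd * rng.standard_normal(
            latent.shape
        )

    mask = np.ones(latent.shape, dtype=bool)
    return ReflectanceStack(
        bands=bands,
        thermal=thermal,
        mask=mask,
        date_label=date_label or stage,
        stage=stage,
    )


def simulate_field(
    config: FieldConfig,
) -> tuple[list[ReflectanceStack], YieldRaster, np.ndarray]:
    """Generate a full synthetic field: one stack per date plus the yield map.

    Returns ``(stacks, yield_raster, latent)``; everything is a pure
    function of ``(config, config.seed)``.
    """
    rng = np.random.default_rng(config.seed)
    latent = simulate_latent(config, rng)
    yield_raster = simulate_yield(latent, config)
    stacks = [
        simulate_reflectance(latent, stage, config, rng, date_label=f"date{i:02d}_{stage}")
        for i, stage in enumerate(config.stage_labels)
    ]
    return stacks, yield_raster, latent
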