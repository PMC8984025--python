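"""Field-simulation configuration.

All spatial quantities live on a 50 cm grid (the working resolution of the
analysis); ``correlation_length`` is given in meters and converted internally.
Every stochastic operation is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

from .errors import ConfigurationError

#: Grid cell edge length in meters (50 cm working resolution).
CELL_SIZE_M = 0.5

#: Vigor-to-reflectance coupling strength per growth stage.  Zero before the
#: crop emerges (bare soil carries no yield signal), rising through tillering,
#: maximal during the reproductive window (booting/flowering), attenuated as
#: grains ripen and leaves senesce.
STAGE_GAINS: dict[str, float] = {
    "pre-emergence": 0.0,
    "tillering": 0.3,
    "panicle-initiation": 0.7,
    "booting": 1.0,
    "flowering": 1.0,
    "grain-fill": 0.5,
}

#: Default acquisition-date stages: the five-date reproductive window used by
#: the spatio-temporal model.
DEFAULT_STAGES: tuple[str, ...] = (
    "tillering",
    "panicle-initiation",
    "booting",
    "flowering",
    "grain-fill",
)


@dataclass(frozen=True)
class TrackNoise:
    """Combine-harvester label-noise artifact: curvilinear additive stripes.

    amplitude : Mg/ha, peak amplitude of the stripe pattern (0 disables it).
    spacing   : cells, distance between successive harvester passes
                (17 cells = 8.5 m header width on the 50 cm grid).
    """

    amplitude: float = 0.3
    spacing: float = 17.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigurationError("track amplitude must be >= 0")
        if self.spacing <= 0:
            raise ConfigurationError("track spacing must be > 0")


@dataclass(frozen=True)
class FieldConfig:
    """Parameters of one simulated rice field.

    The defaults emulate the statistical structure of a 16-ha production
    field: yield 9.06 +/- 0.9 Mg/ha on a 50 cm grid, a 10 m edge buffer
    excluded from the yield map, and multispectral acquisitions whose
    coupling to yield peaks during the reproductive stages.
    """

    height_px: int = 400
    width_px: int = 400
    yield_mean: float = 9.06
    yield_sd: float = 0.9
    correlation_length: float = 15.0  # meters
    n_dates: int = 5
    stage_labels: Sequence[str] = DEFAULT_STAGES
    sensor_noise_sd: float = 0.01  # reflectance units, per band
    label_noise: TrackNoise = field(default_factory=TrackNoise)
    buffer_cells: int = 20  # 10 m at 50 cm resolution
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        if self.yield_sd < 0:
            raise ConfigurationError("yield_sd must be >= 0")
        if self.correlation_length <= 0:
            raise ConfigurationError("correlation_length must be > 0")
        if self.buffer_cells < 0:
            raise ConfigurationError("buffer_cells must be >= 0")
        if self.n_dates < 1:
            raise ConfigurationError("n_dates must be >= 1")
        if len(self.stage_labels) != self.n_dates:
            raise ConfigurationError(
                f"stage_labels has {len(self.stage_labels)} entries for "
                f"n_dates={self.n_dates}"
            )
        if self.sensor_noise_sd < 0:
            raise ConfigurationError("sensor_noise_sd must be >= 0")
        for stage in self.stage_labels:
            if stage not in STAGE_GAINS:
                raise ConfigurationError(
                    f"unknown growth stage {stage!r}; known: "
                    f"{sorted(STAGE_GAINS)}"
                )

    @property
    def correlation_length_cells(self) -> float:
        return self.correlation_length / CELL_SIZE_M

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_labels"] = list(self.stage_labels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FieldConfig":
        d = dict(d)
        if "label_noise" in d and isinstance(d["label_noise"], dict):
            d["label_noise"] = TrackNoise(**d["label_noise"])
        if "stage_labels" in d:
            d["stage_labels"] = tuple(d["stage_labels"])
        return cls(**d)
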