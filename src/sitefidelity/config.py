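"""Configuration objects shared across the pipeline.

`GridSpec` describes a planar raster grid in projected meters (row 0 is the
southernmost row; data arrays are indexed ``[row, col]`` with y increasing
with row index).  `SimulationConfig` parameterizes the synthetic study
system: telemetry, foodscape, reproduction and body-condition generators.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import yaml

__all__ = ["GridSpec", "ConditionCoefs", "SimulationConfig", "load_config"]


@dataclass(frozen=True)
class GridSpec:
    """Regular grid of square cells; (x0, y0) is the lower-left corner."""

    x0: float
    y0: float
    cell_size: float
    ncols: int
    nrows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.ncols <= 0 or self.nrows <= 0:
            raise ValueError(
                f"grid dimensions must be positive, got {self.ncols}x{self.nrows}"
            )

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.ncols) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.nrows) + 0.5) * self.cell_size

    @property
    def xmax(self) -> float:
        return self.x0 + self.ncols * self.cell_size

    @property
    def ymax(self) -> float:
        return self.y0 + self.nrows * self.cell_size

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size**2

    def index_of(self, x, y):
        """Map coordinates to (row, col); points outside return -1."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((y - self.y0) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    @classmethod
    def from_extent(
        cls,
        xmin: float,
        xmax: float,
        ymin: float,
        ymax: float,
        cell_size: float,
        pad: float = 0.0,
    ) -> "GridSpec":
        xmin, xmax = xmin - pad, xmax + pad
        ymin, ymax = ymin - pad, ymax + pad
        ncols = max(1, int(np.ceil((xmax - xmin) / cell_size)))
        nrows = max(1, int(np.ceil((ymax - ymin) / cell_size)))
        return cls(x0=xmin, y0=ymin, cell_size=cell_size, ncols=ncols, nrows=nrows)


@dataclass(frozen=True)
class ConditionCoefs:
    """Generating coefficients of the autumn body-fat model (percent IFBFat).

    autumn = intercept + recruit_effect * recruited
             + fidelity_effect * z(ln distance) + spring_fat_effect * spring
             + N(0, residual_sd)
    """

    intercept: float = 13.0
    recruit_effect: float = -3.0
    fidelity_effect: float = 0.0
    spring_fat_effect: float = 0.3
    residual_sd: float = 1.5
    spring_fat_mean: float = 8.0
    spring_fat_sd: float = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study-system parameters for the synthetic data generators.

    Movement is an Ornstein–Uhlenbeck walk attracted to a yearly activity
    center; consecutive-year centers are displaced by ``ou_center_shift_m``
    in a uniformly random direction, which dials true inter-annual fidelity.
    The foodscape is a daily stack of suitable-biomass rasters with
    exponential spatial covariance, per-pixel AR(1) temporal persistence and
    a seasonal mean curve.  Neonate survival is exponential with a
    log-linear maternal-fidelity effect; body condition is a linear model
    on recruitment, fidelity and spring fat.
    """

    seed: int = 1
    n_animals: int = 12
    years: tuple = (2019, 2020)
    season_start: tuple = (6, 1)  # (month, day), alpine default
    season_end: tuple = (9, 1)
    fix_interval_h: float = 1.0
    grid: GridSpec = field(
        default_factory=lambda: GridSpec(
            x0=0.0, y0=0.0, cell_size=250.0, ncols=40, nrows=40
        )
    )
    # movement
    ou_center_shift_m: float = 300.0
    ou_attraction: float = 0.1  # 1/h mean reversion
    ou_diffusion: float = 5.0e4  # m^2/h
    loc_error_sd_m: float = 20.0
    thinning_fraction: float = 0.0  # optional fix-failure rate
    # foodscape
    field_spatial_range_m: float = 1000.0
    field_temporal_ar: float = 0.9
    field_innovation_sd: float = 0.1
    field_seasonal_amplitude: float = 0.3
    field_base_level: float = 1.0
    # reproduction
    parturition_start: tuple = (5, 15)
    parturition_end: tuple = (6, 15)
    hazard_rate_per_day: float = 0.005
    hazard_fidelity_beta: float = 0.0
    survival_window_days: int = 120
    # condition
    condition_coefs: ConditionCoefs = field(default_factory=ConditionCoefs)

    def __post_init__(self) -> None:
        if not 0.0 <= self.field_temporal_ar <= 1.0:
            raise ValueError("field_temporal_ar must lie in [0, 1]")
        if self.ou_attraction <= 0:
            raise ValueError("ou_attraction must be positive")
        if self.ou_center_shift_m < 0 or self.ou_diffusion < 0:
            raise ValueError("ou_center_shift_m and ou_diffusion must be >= 0")
        if self.loc_error_sd_m < 0 or self.field_innovation_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.hazard_rate_per_day <= 0:
            raise ValueError("hazard_rate_per_day must be positive")
        if self.fix_interval_h <= 0 or 24.0 % self.fix_interval_h != 0:
            raise ValueError("fix_interval_h must be positive and divide 24 h")

    def season_dates(self, year: int) -> tuple[date, date]:
        """Half-open [start, end) season window for one calendar year."""
        return (
            date(year, *self.season_start),
            date(year, *self.season_end),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "grid" in d and isinstance(d["grid"], dict):
            d["grid"] = GridSpec(**d["grid"])
        if "condition_coefs" in d and isinstance(d["condition_coefs"], dict):
            d["condition_coefs"] = ConditionCoefs(**d["condition_coefs"])
        for key in ("years", "season_start", "season_end", "parturition_start", "parturition_end"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def load_config(path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(raw)
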