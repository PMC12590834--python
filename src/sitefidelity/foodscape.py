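"""Foodscape quality and Colwell constancy within home ranges.

Colwell's constancy of a set of values is C = 1 - H / ln(n), where H is
the Shannon entropy of the proportions of values falling in n evenly
spaced bins (here n = 100 on [0, 1]).  C = 1 when every value occupies a
single bin (perfect constancy) and C = 0 when values spread uniformly
over all bins.  Temporal constancy is computed per pixel over days and
averaged across home-range pixels; spatial constancy is computed per day
over home-range pixels and averaged across days.  Mean scaled suitable
biomass within the home range serves as the quality metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date

import numpy as np

from .config import GridSpec
from .dbbmm import HomeRange
from .tracks import IntervalWindow

__all__ = [
    "FoodscapeStack",
    "ScaledStack",
    "ConstancyResult",
    "scale_stack",
    "shannon_entropy",
    "colwell_constancy",
    "temporal_constancy_hr",
    "spatial_constancy_hr",
    "mean_biomass_hr",
    "constancy_for_home_range",
]

N_BINS_DEFAULT = 100


@dataclass(frozen=True)
class FoodscapeStack:
    """Date-indexed raster cube of suitable biomass on a shared grid."""

    grid: GridSpec
    dates: tuple  # datetime.date, sorted, one per layer
    data: np.ndarray  # [n_days, nrows, ncols]

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.dates), self.grid.nrows, self.grid.ncols):
            raise ValueError("data shape does not match dates/grid")
        if list(self.dates) != sorted(self.dates):
            raise ValueError("dates must be sorted")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite biomass values")

    def layer(self, day: date) -> np.ndarray:
        return self.data[self.dates.index(day)]

    def slice_interval(self, interval: IntervalWindow) -> "FoodscapeStack":
        keep = [i for i, d in enumerate(self.dates) if interval.start <= d < interval.end]
        if not keep:
            raise ValueError(
                f"stack has no layers within {interval.start}..{interval.end}"
            )
        return FoodscapeStack(
            self.grid, tuple(self.dates[i] for i in keep), self.data[keep]
        )


@dataclass(frozen=True)
class ScaledStack(FoodscapeStack):
    """Foodscape min-max scaled to [0, 1] with the scaling constants kept."""

    scale_min: float = 0.0
    scale_max: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.min() < -1e-12 or self.data.max() > 1.0 + 1e-12:
            raise ValueError("scaled values must lie in [0, 1]")

    def slice_interval(self, interval: IntervalWindow) -> "ScaledStack":
        base = FoodscapeStack.slice_interval(self, interval)
        return ScaledStack(
            base.grid, base.dates, base.data,
            scale_min=self.scale_min, scale_max=self.scale_max,
        )

    def unscale(self, values: np.ndarray) -> np.ndarray:
        return values * (self.scale_max - self.scale_min) + self.scale_min


@dataclass(frozen=True)
class ConstancyResult:
    animal_id: str
    interval: IntervalWindow
    temporal_C: float
    spatial_C: float
    mean_biomass: float
    n_pixels: int
    n_days: int


def scale_stack(stacks) -> list[ScaledStack]:
    """Global min-max scaling across all layers, dates and sites in the run.

    Accepts one stack or a sequence; returns the same number of
    `ScaledStack` objects sharing a single (min, max) record so that
    quality and predictability are comparable across sites.
    """
    single = isinstance(stacks, FoodscapeStack)
    group = [stacks] if single else list(stacks)
    lo = min(float(s.data.min()) for s in group)
    hi = max(float(s.data.max()) for s in group)
    out = []
    for s in group:
        if hi == lo:
            warnings.warn("degenerate constant foodscape; scaled values set to 1.0")
            scaled = np.ones_like(s.data)
        else:
            scaled = (s.data - lo) / (hi - lo)
        out.append(ScaledStack(s.grid, s.dates, scaled, scale_min=lo, scale_max=hi))
    return out[0] if single else out


def shannon_entropy(P) -> float:
    """H = -sum(P_i ln P_i) with 0 ln 0 := 0; requires P >= 0 summing to 1."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("proportions must be nonnegative")
    if not np.isclose(P.sum(), 1.0, atol=1e-9):
        raise ValueError(f"proportions sum to {P.sum()}, not 1")
    nz = P[P > 0]
    return float(-(nz * np.log(nz)).sum())


def _bin_counts(values: np.ndarray, n_bins: int) -> np.ndarray:
    # half-open [l, u) bins on [0, 1]; the last bin closes at 1.0
    idx = np.minimum((values * n_bins).astype(int), n_bins - 1)
    return np.bincount(idx, minlength=n_bins)


def colwell_constancy(values, n_bins: int = N_BINS_DEFAULT) -> float:
    """C = 1 - H/ln(n) of values in [0, 1] binned into n even intervals."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("constancy of an empty series is undefined")
    if values.min() < -1e-12 or values.max() > 1.0 + 1e-12:
        raise ValueError("values must lie in [0, 1] (scale the stack first)")
    counts = _bin_counts(np.clip(values, 0.0, 1.0), n_bins)
    P = counts / counts.sum()
    H = shannon_entropy(P)
    return float(1.0 - H / np.log(n_bins))


def _hr_pixel_mask(stack: FoodscapeStack, hr: HomeRange) -> np.ndarray:
    """Home-range membership of foodscape pixels by cell-center containment."""
    mask = hr.mask_on_grid(stack.grid)
    if not mask.any():
        raise ValueError("home range covers no foodscape pixels")
    return mask


def temporal_constancy_hr(
    stack: ScaledStack,
    hr: HomeRange,
    interval: IntervalWindow,
    n_bins: int = N_BINS_DEFAULT,
):
    """Per-pixel constancy over days, averaged across home-range pixels.

    Returns (mean C, per-pixel C values in mask order).
    """
    sub = stack.slice_interval(interval)
    mask = _hr_pixel_mask(sub, hr)
    series = sub.data[:, mask]  # [n_days, n_pixels]
    if series.shape[0] == 1:
        warnings.warn("single-day interval: temporal constancy degenerate (C = 1)")
    per_pixel = np.array(
        [colwell_constancy(series[:, j], n_bins) for j in range(series.shape[1])]
    )
    return float(per_pixel.mean()), per_pixel


def spatial_constancy_hr(
    stack: ScaledStack,
    hr: HomeRange,
    interval: IntervalWindow,
    n_bins: int = N_BINS_DEFAULT,
):
    """Per-day constancy over home-range pixels, averaged across days.

    Returns (mean C, per-day C series).
    """
    sub = stack.slice_interval(interval)
    mask = _hr_pixel_mask(sub, hr)
    if int(mask.sum()) == 1:
        warnings.warn("single-pixel home range: spatial constancy degenerate (C = 1)")
    per_day = np.array(
        [colwell_constancy(layer[mask], n_bins) for layer in sub.data]
    )
    return float(per_day.mean()), per_day


def mean_biomass_hr(
    stack: ScaledStack, hr: HomeRange, interval: IntervalWindow
) -> float:
    """Mean scaled suitable biomass over in-range pixels and interval days."""
    sub = stack.slice_interval(interval)
    mask = _hr_pixel_mask(sub, hr)
    return float(sub.data[:, mask].mean())


def constancy_for_home_range(
    stack: ScaledStack,
    hr: HomeRange,
    interval: IntervalWindow,
    animal_id: str,
    n_bins: int = N_BINS_DEFAULT,
) -> ConstancyResult:
    """Bundle temporal/spatial constancy and quality for one animal-interval."""
    try:
        temporal, per_pixel = temporal_constancy_hr(stack, hr, interval, n_bins)
        spatial, per_day = spatial_constancy_hr(stack, hr, interval, n_bins)
    except ValueError as exc:
        raise ValueError(f"{animal_id} {interval.key}: {exc}") from exc
    return ConstancyResult(
        animal_id=animal_id,
        interval=interval,
        temporal_C=temporal,
        spatial_C=spatial,
        mean_biomass=mean_biomass_hr(stack, hr, interval),
        n_pixels=len(per_pixel),
        n_days=len(per_day),
    )
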