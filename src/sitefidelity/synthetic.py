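"""Synthetic study system with known ground truth.

Emulates the data structures of a multi-year bighorn telemetry study:
hourly GPS fixes over a summer season, 250-m daily suitable-biomass
rasters, neonate survival histories and paired spring/autumn body-fat
measurements.  Every generator is seeded from `SimulationConfig.seed`
through independent substreams, so a fixed seed reproduces the dataset
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .foodscape import FoodscapeStack
from .recruitment import NeonateRecord, annual_success
from .tracks import Trajectory

__all__ = [
    "SyntheticDataset",
    "generate_foodscape",
    "simulate_trajectories",
    "simulate_reproduction",
    "simulate_condition",
    "make_dataset",
    "make_analysis_table",
]

_STREAMS = {"foodscape": 0, "trajectories": 1, "reproduction": 2, "condition": 3}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class SyntheticDataset:
    trajectories: tuple
    foodscape: FoodscapeStack
    neonates: tuple
    condition: pd.DataFrame
    truth: dict


def _season_days(config: SimulationConfig) -> list[date]:
    days = []
    for year in config.years:
        start, end = config.season_dates(year)
        days.extend(start + timedelta(days=k) for k in range((end - start).days))
    return days


def generate_foodscape(config: SimulationConfig) -> FoodscapeStack:
    """Daily suitable-biomass rasters with tunable structure.

    Spatial structure: stationary Gaussian random field with exponential
    covariance (range ``field_spatial_range_m``), generated by Cholesky
    factorization of the grid covariance.  Temporal structure: per-pixel
    AR(1) with coefficient ``field_temporal_ar`` and innovation sd
    ``field_innovation_sd`` (innovations share the spatial field).  A
    half-sine seasonal mean curve is added and values are floored at 0.
    """
    rng = _rng(config, "foodscape")
    grid = config.grid
    days = _season_days(config)
    xc, yc = np.meshgrid(grid.x_centers, grid.y_centers)
    pts = np.column_stack([xc.ravel(), yc.ravel()])
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    cov = np.exp(-d / config.field_spatial_range_m)
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(len(pts)))

    def draw_field() -> np.ndarray:
        return (L @ rng.standard_normal(len(pts))).reshape(grid.nrows, grid.ncols)

    ar = config.field_temporal_ar
    sd = config.field_innovation_sd
    # stationary start where it exists; random-walk scale otherwise
    z = draw_field() * (sd / np.sqrt(1.0 - ar**2) if ar < 1.0 else sd)
    layers = np.empty((len(days), grid.nrows, grid.ncols))
    season_len = max(len(days) // max(len(config.years), 1), 1)
    for i, day in enumerate(days):
        start, end = config.season_dates(day.year)
        frac = (day - start).days / max((end - start).days, 1)
        seasonal = config.field_seasonal_amplitude * np.sin(np.pi * frac)
        layers[i] = np.maximum(config.field_base_level + seasonal + z, 0.0)
        z = ar * z + sd * draw_field()
    return FoodscapeStack(grid, tuple(days), layers)


def _simulate_trajectories(config: SimulationConfig):
    rng = _rng(config, "trajectories")
    grid = config.grid
    lx, ly = grid.xmax - grid.x0, grid.ymax - grid.y0
    dt = config.fix_interval_h
    theta = config.ou_attraction
    sigma_st2 = config.ou_diffusion / (2.0 * theta)
    phi = np.exp(-theta * dt)
    step_sd = np.sqrt(sigma_st2 * (1.0 - phi**2))

    trajectories, centers = [], {}
    for a in range(config.n_animals):
        animal_id = f"F{a + 1:02d}"
        center = np.array(
            [
                grid.x0 + lx * rng.uniform(0.25, 0.75),
                grid.y0 + ly * rng.uniform(0.25, 0.75),
            ]
        )
        for yi, year in enumerate(config.years):
            if yi > 0:
                ang = rng.uniform(0.0, 2.0 * np.pi)
                center = center + config.ou_center_shift_m * np.array(
                    [np.cos(ang), np.sin(ang)]
                )
            centers[(animal_id, year)] = center.copy()
            start, end = config.season_dates(year)
            n_fix = int((end - start).days * 24 / dt)
            pos = center + np.sqrt(sigma_st2) * rng.standard_normal(2)
            xs = np.empty((n_fix, 2))
            for i in range(n_fix):
                xs[i] = pos
                pos = center + phi * (pos - center) + step_sd * rng.standard_normal(2)
            obs = xs + config.loc_error_sd_m * rng.standard_normal(xs.shape)
            ts = pd.to_datetime(
                [
                    datetime.combine(start, datetime.min.time(), tzinfo=timezone.utc)
                    + timedelta(hours=i * dt)
                    for i in range(n_fix)
                ]
            )
            keep = np.ones(n_fix, dtype=bool)
            if config.thinning_fraction > 0:
                keep = rng.uniform(size=n_fix) >= config.thinning_fraction
            df = pd.DataFrame({"timestamp": ts[keep], "x": obs[keep, 0], "y": obs[keep, 1]})
            trajectories.append(Trajectory(animal_id=animal_id, fixes=df, site_id="S1"))
    return trajectories, centers


def simulate_trajectories(config: SimulationConfig):
    """Ornstein-Uhlenbeck tracks attracted to yearly centers.

    Consecutive-year centers are displaced by ``ou_center_shift_m`` in a
    uniformly random direction; i.i.d. Gaussian location error is added.
    One trajectory per animal-year.
    """
    return _simulate_trajectories(config)[0]


def _centroid_fidelity(trajectories) -> pd.DataFrame:
    """Inter-annual centroid displacement per mother-year (m)."""
    rows = []
    by_key = {}
    for tr in trajectories:
        year = int(tr.fixes["timestamp"].dt.year.iloc[0])
        by_key[(tr.animal_id, year)] = tr.xy.mean(axis=0)
    for (animal, year), c in sorted(by_key.items()):
        prev = by_key.get((animal, year - 1))
        dist = float(np.linalg.norm(c - prev)) if prev is not None else np.nan
        rows.append({"animal_id": animal, "year": year, "distance_m": dist})
    return pd.DataFrame(rows)


def _standardize_log(dist: pd.Series) -> pd.Series:
    z = np.log(dist + 1.0)
    ok = z.notna()
    if ok.sum() >= 2 and z[ok].std(ddof=0) > 0:
        z = (z - z[ok].mean()) / z[ok].std(ddof=0)
    else:
        z = z * 0.0
    return z.fillna(0.0)


def simulate_reproduction(config: SimulationConfig, trajectories=None):
    """One neonate per mother-year under an exponential fidelity-linked hazard.

    h = hazard_rate_per_day * exp(hazard_fidelity_beta * z), where z is the
    mother's standardized log inter-annual centroid displacement (0 when no
    previous year exists or no trajectories are given).  Survivors past the
    120-day window are censored at day 120.
    """
    rng = _rng(config, "reproduction")
    if trajectories is None:
        keys = [
            (f"F{a + 1:02d}", year)
            for a in range(config.n_animals)
            for year in config.years
        ]
        z = pd.Series(0.0, index=range(len(keys)))
        frame = pd.DataFrame(keys, columns=["animal_id", "year"]).assign(z=z)
    else:
        frame = _centroid_fidelity(trajectories)
        frame["z"] = _standardize_log(frame["distance_m"])
    records = []
    for row in frame.itertuples():
        p_start = date(int(row.year), *config.parturition_start)
        p_days = (date(int(row.year), *config.parturition_end) - p_start).days
        birth = p_start + timedelta(days=int(rng.integers(0, p_days + 1)))
        rate = config.hazard_rate_per_day * np.exp(
            config.hazard_fidelity_beta * row.z
        )
        t_death = rng.exponential(1.0 / rate)
        if t_death >= config.survival_window_days:
            fate = "survived_window"
            end = birth + timedelta(days=config.survival_window_days)
        else:
            fate = "died"
            end = birth + timedelta(days=int(round(t_death)))
        records.append(
            NeonateRecord(
                mother_id=row.animal_id,
                year=int(row.year),
                birth_date=birth,
                end_date=end,
                fate=fate,
                maternal_fidelity_z=float(row.z),
            )
        )
    return records


def simulate_condition(
    config: SimulationConfig,
    recruitment: pd.DataFrame,
    fidelity: pd.DataFrame,
) -> pd.DataFrame:
    """Paired spring/autumn percent ingesta-free body fat per female-year.

    autumn = intercept + recruit_effect * recruited + fidelity_effect * z
             + spring_fat_effect * spring + Gaussian noise.
    """
    rng = _rng(config, "condition")
    coefs = config.condition_coefs
    df = recruitment.merge(fidelity, on=["animal_id", "year"], how="left")
    z = _standardize_log(df["distance_m"]) if "distance_m" in df else pd.Series(0.0, index=df.index)
    spring = rng.normal(coefs.spring_fat_mean, coefs.spring_fat_sd, len(df))
    noise = rng.normal(0.0, coefs.residual_sd, len(df))
    autumn = (
        coefs.intercept
        + coefs.recruit_effect * df["recruited"].astype(float).to_numpy()
        + coefs.fidelity_effect * z.to_numpy()
        + coefs.spring_fat_effect * spring
        + noise
    )
    return pd.DataFrame(
        {
            "animal_id": df["animal_id"],
            "year": df["year"],
            "spring_fat_pct": spring,
            "autumn_fat_pct": autumn,
        }
    )


def make_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Bundle all generators under one seed with a ground-truth record."""
    trajectories, centers = _simulate_trajectories(config)
    foodscape = generate_foodscape(config)
    neonates = simulate_reproduction(config, trajectories)
    recruitment = pd.DataFrame(
        [
            {
                "animal_id": r.mother_id,
                "year": r.year,
                "recruited": annual_success(r) == "success",
            }
            for r in neonates
        ]
    )
    fidelity = _centroid_fidelity(trajectories)
    condition = simulate_condition(config, recruitment, fidelity)
    truth = config.to_dict()
    truth["centers"] = {
        f"{animal}:{year}": [float(c[0]), float(c[1])]
        for (animal, year), c in centers.items()
    }
    return SyntheticDataset(
        trajectories=tuple(trajectories),
        foodscape=foodscape,
        neonates=tuple(neonates),
        condition=condition,
        truth=truth,
    )


def make_analysis_table(
    n_rows: int = 300,
    n_animals: int = 30,
    betas: dict | None = None,
    intercept: float = 6.0,
    re_sd: float = 0.5,
    resid_sd: float = 1.0,
    recruit_prob: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Analysis-table generator with known fixed effects, for recovery tests.

    Continuous covariates are independent standard normals (already on the
    standardized scale); ``recruit`` is Bernoulli.  The response is
    ln(distance) = intercept + X beta + animal intercept + noise.
    """
    if betas is None:
        betas = {
            "spatial_C": 0.3,
            "temporal_C": 0.2,
            "mean_biomass": -0.2,
            "recruit": 0.4,
            "hr_area_km2": -0.3,
        }
    rng = np.random.default_rng(seed)
    animals = rng.integers(0, n_animals, n_rows)
    re = rng.normal(0.0, re_sd, n_animals)
    df = pd.DataFrame(
        {
            "animal_id": [f"F{a:02d}" for a in animals],
            "site_id": "S1",
            "scale": "annual",
            "year": 2020,
            "index": np.arange(n_rows),
            "spatial_C": rng.standard_normal(n_rows),
            "temporal_C": rng.standard_normal(n_rows),
            "mean_biomass": rng.standard_normal(n_rows),
            "hr_area_km2": rng.standard_normal(n_rows),
            "recruit": (rng.uniform(size=n_rows) < recruit_prob).astype(int),
        }
    )
    y = intercept + re[animals] + rng.normal(0.0, resid_sd, n_rows)
    for term, beta in betas.items():
        y = y + beta * df[term].to_numpy()
    df["log_distance"] = y
    df["group"] = df["animal_id"]
    return df
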