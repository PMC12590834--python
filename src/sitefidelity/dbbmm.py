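"""Dynamic Brownian bridge movement model (dBBMM) utilization distributions.

The Brownian bridge between consecutive fixes a, b places the animal at
time t in between at an isotropic Gaussian centered on the chord at
alpha = (t - t_a)/(t_b - t_a) with variance

    T * alpha * (1 - alpha) * sigma2m + (1 - alpha)^2 * delta_a^2
    + alpha^2 * delta_b^2,

where sigma2m is the Brownian motion variance (m^2/s) and delta the
telemetry location-error sd (m).  The *dynamic* model lets sigma2m vary
along the track: a window of `window` fixes slides one fix at a time; in
each window a single-sigma2m model competes by BIC against models with one
breakpoint whose pieces each retain at least `margin` fixes, sigma2m in
each piece maximizing the leave-one-out likelihood of the interior
odd-indexed fixes under the bridge implied by their neighbors.  A
segment's final sigma2m is the mean over all windows covering it.

The utilization distribution (UD) is the time-weighted average of the
bridge densities along the track; the home range is the smallest set of
cells, by descending density, enclosing a target probability mass
(default isopleth 0.99).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .config import GridSpec
from .tracks import Trajectory

__all__ = [
    "MotionVarianceSeries",
    "UtilizationDistribution",
    "HomeRange",
    "estimate_motion_variance",
    "segment_bridge_density",
    "compute_ud",
    "isopleth_home_range",
    "fit_home_range",
]

SIGMA2_BOUNDS = (1e-6, 1e4)  # m^2/s, optimizer box


@dataclass(frozen=True)
class MotionVarianceSeries:
    """Per-segment motion variance aligned to segments between fixes."""

    sigma2m: np.ndarray  # length n_fixes - 1, m^2/s
    delta_m: np.ndarray  # length n_fixes, per-fix location-error sd

    def __post_init__(self) -> None:
        if len(self.sigma2m) != len(self.delta_m) - 1:
            raise ValueError("sigma2m must have length n_fixes - 1")
        if np.any(self.sigma2m <= 0):
            raise ValueError("sigma2m must be positive")


@dataclass(frozen=True)
class UtilizationDistribution:
    grid: GridSpec
    p: np.ndarray  # [nrows, ncols], sums to 1

    def __post_init__(self) -> None:
        if self.p.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError("probability array does not match grid")
        total = float(self.p.sum())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"UD mass {total} != 1")


@dataclass(frozen=True)
class HomeRange:
    ud: UtilizationDistribution
    isopleth_level: float
    mask: np.ndarray  # [nrows, ncols] bool

    @property
    def area_km2(self) -> float:
        return float(self.mask.sum()) * self.ud.grid.cell_area_m2 / 1e6

    @property
    def enclosed_mass(self) -> float:
        return float(self.ud.p[self.mask].sum())

    def mask_on_grid(self, grid: GridSpec) -> np.ndarray:
        """Resample the isopleth mask to another grid by cell-center containment."""
        xc, yc = np.meshgrid(grid.x_centers, grid.y_centers)
        row, col = self.ud.grid.index_of(xc.ravel(), yc.ravel())
        out = np.zeros(row.size, dtype=bool)
        inside = row >= 0
        out[inside] = self.mask[row[inside], col[inside]]
        return out.reshape(grid.nrows, grid.ncols)


def _piece_stats(t, xy, delta):
    """Leave-one-out statistics for interior odd-indexed fixes of a piece."""
    j = np.arange(1, len(t) - 1, 2)
    a, b = j - 1, j + 1
    T = t[b] - t[a]
    alpha = (t[j] - t[a]) / T
    mean = xy[a] + alpha[:, None] * (xy[b] - xy[a])
    r2 = ((xy[j] - mean) ** 2).sum(axis=1)
    bridge = T * alpha * (1.0 - alpha)
    err = (
        (1.0 - alpha) ** 2 * delta[a] ** 2
        + alpha**2 * delta[b] ** 2
        + delta[j] ** 2
    )
    return bridge, err, r2


def _fit_sigma2(bridge, err, r2):
    """Maximize the odd-point likelihood over sigma2m on a log scale."""
    lo, hi = np.log(SIGMA2_BOUNDS[0]), np.log(SIGMA2_BOUNDS[1])

    def nll(log_s2):
        v = bridge * np.exp(log_s2) + err
        return float(np.sum(np.log(2.0 * np.pi * v) + r2 / (2.0 * v)))

    res = minimize_scalar(
        nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
    )
    return float(np.exp(res.x)), float(res.fun), len(r2)


def estimate_motion_variance(
    traj: Trajectory,
    window: int = 7,
    margin: int = 3,
    delta_m: float = 20.0,
) -> MotionVarianceSeries:
    """Windowed BIC-selected motion variance along a trajectory."""
    n = len(traj)
    if n < 2:
        raise ValueError("need at least 2 fixes")
    t = traj.times_s
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    xy = traj.xy
    delta = np.full(n, float(delta_m))

    if n < window:
        warnings.warn(
            f"{traj.animal_id}: {n} fixes < window {window}; single global sigma2m"
        )
        s2, _, _ = _fit_sigma2(*_piece_stats(t, xy, delta))
        return MotionVarianceSeries(np.full(n - 1, s2), delta)

    sums = np.zeros(n - 1)
    counts = np.zeros(n - 1)
    # break positions must leave >= margin fixes (and >= 3, for an interior
    # odd point) on each side of the split fix
    m_eff = max(margin, 3)
    for s in range(n - window + 1):
        tw = t[s : s + window]
        xw = xy[s : s + window]
        dw = delta[s : s + window]
        s2_full, nll_full, n_pts = _fit_sigma2(*_piece_stats(tw, xw, dw))
        best_bic = 2.0 * nll_full + 1.0 * np.log(n_pts)
        best_assign = np.full(window - 1, s2_full)
        for k in range(m_eff - 1, window - m_eff + 1):
            sl, nl, ml = _fit_sigma2(*_piece_stats(tw[: k + 1], xw[: k + 1], dw[: k + 1]))
            sr, nr, mr = _fit_sigma2(*_piece_stats(tw[k:], xw[k:], dw[k:]))
            bic = 2.0 * (nl + nr) + 2.0 * np.log(ml + mr)
            if bic < best_bic:
                best_bic = bic
                assign = np.empty(window - 1)
                assign[:k] = sl
                assign[k:] = sr
                best_assign = assign
        sums[s : s + window - 1] += best_assign
        counts[s : s + window - 1] += 1.0
    return MotionVarianceSeries(sums / counts, delta)


def segment_bridge_density(
    t_a: float,
    xy_a,
    t_b: float,
    xy_b,
    t: float,
    sigma2m: float,
    delta_a: float,
    delta_b: float,
    grid: GridSpec,
) -> np.ndarray:
    """Bridge density (per m^2) over the grid at one time within a segment."""
    T = t_b - t_a
    if T <= 0:
        raise ValueError("segment has zero or negative time span")
    if not (t_a < t < t_b):
        raise ValueError("t must lie strictly between the endpoint times")
    alpha = (t - t_a) / T
    mu = np.asarray(xy_a, float) + alpha * (np.asarray(xy_b, float) - np.asarray(xy_a, float))
    var = (
        T * alpha * (1.0 - alpha) * sigma2m
        + (1.0 - alpha) ** 2 * delta_a**2
        + alpha**2 * delta_b**2
    )
    dx = grid.x_centers - mu[0]
    dy = grid.y_centers - mu[1]
    gx = np.exp(-(dx**2) / (2.0 * var))
    gy = np.exp(-(dy**2) / (2.0 * var))
    return np.outer(gy, gx) / (2.0 * np.pi * var)


def _accumulate_gaussian(mass, grid, mu, var, weight, trunc_sd=5.0):
    """Add `weight` times an isotropic Gaussian cell-mass patch in place."""
    if var <= 0:
        row, col = grid.index_of(mu[0], mu[1])
        if row >= 0:
            mass[row, col] += weight
        return
    sd = np.sqrt(var)
    half = trunc_sd * sd
    c0 = max(0, int(np.floor((mu[0] - half - grid.x0) / grid.cell_size)))
    c1 = min(grid.ncols, int(np.ceil((mu[0] + half - grid.x0) / grid.cell_size)) + 1)
    r0 = max(0, int(np.floor((mu[1] - half - grid.y0) / grid.cell_size)))
    r1 = min(grid.nrows, int(np.ceil((mu[1] + half - grid.y0) / grid.cell_size)) + 1)
    if c0 >= c1 or r0 >= r1:
        return
    dx = grid.x_centers[c0:c1] - mu[0]
    dy = grid.y_centers[r0:r1] - mu[1]
    gx = np.exp(-(dx**2) / (2.0 * var))
    gy = np.exp(-(dy**2) / (2.0 * var))
    patch = np.outer(gy, gx) * (grid.cell_area_m2 / (2.0 * np.pi * var))
    mass[r0:r1, c0:c1] += weight * patch


def _max_bridge_sd(t, mvs: MotionVarianceSeries) -> float:
    dt = np.diff(t)
    var = dt * 0.25 * mvs.sigma2m + np.max(mvs.delta_m) ** 2
    return float(np.sqrt(np.max(var))) if len(var) else float(np.max(mvs.delta_m))


def compute_ud(
    traj: Trajectory,
    mvs: MotionVarianceSeries,
    grid: GridSpec | None = None,
    n_integration_points: int = 10,
    cell_size: float = 50.0,
    gap_max: float = 6.0,
) -> UtilizationDistribution:
    """Time-weighted UD over the grid from per-segment bridge densities.

    Segments spanning more than ``gap_max`` times the nominal fix interval
    contribute density only at their endpoint fixes, so telemetry outages
    do not fabricate corridors.
    """
    n = len(traj)
    if len(mvs.sigma2m) != n - 1:
        raise ValueError("motion variance series not aligned with trajectory")
    t = traj.times_s
    xy = traj.xy
    pad = 3.0 * _max_bridge_sd(t, mvs)
    if grid is None:
        grid = GridSpec.from_extent(
            xy[:, 0].min(), xy[:, 0].max(), xy[:, 1].min(), xy[:, 1].max(),
            cell_size=cell_size, pad=max(pad, cell_size),
        )
    else:
        if (
            xy[:, 0].min() - pad < grid.x0
            or xy[:, 0].max() + pad > grid.xmax
            or xy[:, 1].min() - pad < grid.y0
            or xy[:, 1].max() + pad > grid.ymax
        ):
            warnings.warn("grid does not cover the 3-sigma envelope; expanding")
            grid = GridSpec.from_extent(
                min(grid.x0, xy[:, 0].min() - pad),
                max(grid.xmax, xy[:, 0].max() + pad),
                min(grid.y0, xy[:, 1].min() - pad),
                max(grid.ymax, xy[:, 1].max() + pad),
                cell_size=grid.cell_size,
            )

    dt = np.diff(t)
    dt_nominal = float(np.median(dt))
    mass = np.zeros((grid.nrows, grid.ncols))
    K = n_integration_points
    for i in range(n - 1):
        if dt[i] > gap_max * dt_nominal:
            for end in (i, i + 1):
                _accumulate_gaussian(
                    mass, grid, xy[end], mvs.delta_m[end] ** 2, dt_nominal / 2.0
                )
            continue
        for m in range(K):
            alpha = (m + 0.5) / K
            mu = xy[i] + alpha * (xy[i + 1] - xy[i])
            var = (
                dt[i] * alpha * (1.0 - alpha) * mvs.sigma2m[i]
                + (1.0 - alpha) ** 2 * mvs.delta_m[i] ** 2
                + alpha**2 * mvs.delta_m[i + 1] ** 2
            )
            _accumulate_gaussian(mass, grid, mu, var, dt[i] / K)
    total = mass.sum()
    if total <= 0:
        raise ValueError("empty utilization distribution")
    return UtilizationDistribution(grid, mass / total)


def isopleth_home_range(ud: UtilizationDistribution, level: float = 0.99) -> HomeRange:
    """Smallest cell set, by descending density, enclosing >= `level` mass."""
    if not 0.0 < level <= 1.0:
        raise ValueError(f"isopleth level must be in (0, 1], got {level}")
    flat = ud.p.ravel()
    order = np.argsort(flat)[::-1]
    if level == 1.0:
        n_keep = int((flat > 0).sum())
    else:
        cum = np.cumsum(flat[order])
        n_keep = int(np.searchsorted(cum, level - 1e-12)) + 1
        n_keep = min(n_keep, int((flat > 0).sum()))
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:n_keep]] = True
    return HomeRange(ud, level, mask.reshape(ud.p.shape))


def fit_home_range(
    traj: Trajectory,
    window: int = 7,
    margin: int = 3,
    delta_m: float = 20.0,
    level: float = 0.99,
    grid: GridSpec | None = None,
    cell_size: float = 50.0,
    n_integration_points: int = 10,
) -> HomeRange:
    """Convenience chain: motion variance -> UD -> isopleth home range."""
    mvs = estimate_motion_variance(traj, window=window, margin=margin, delta_m=delta_m)
    ud = compute_ud(
        traj, mvs, grid=grid, cell_size=cell_size,
        n_integration_points=n_integration_points,
    )
    return isopleth_home_range(ud, level=level)
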