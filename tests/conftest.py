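from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest

from sitefidelity.config import GridSpec
from sitefidelity.dbbmm import HomeRange, UtilizationDistribution
from sitefidelity.foodscape import ScaledStack
from sitefidelity.tracks import Trajectory


def traj_from_xy(xy, start=datetime(2020, 6, 1, tzinfo=timezone.utc), dt_h=1.0,
                 animal_id="T1", site_id="S1"):
    """Trajectory from an (n, 2) coordinate array at a fixed interval."""
    xy = np.asarray(xy, dtype=float)
    ts = pd.to_datetime([start + timedelta(hours=i * dt_h) for i in range(len(xy))])
    return Trajectory(
        animal_id=animal_id,
        fixes=pd.DataFrame({"timestamp": ts, "x": xy[:, 0], "y": xy[:, 1]}),
        site_id=site_id,
    )


def brownian_track(n, sigma2, dt_s=3600.0, seed=0, origin=(0.0, 0.0)):
    """Pure Brownian motion with per-axis step variance sigma2 * dt."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(sigma2 * dt_s), (n - 1, 2))
    xy = np.vstack([np.asarray(origin), np.asarray(origin) + np.cumsum(steps, axis=0)])
    return traj_from_xy(xy, dt_h=dt_s / 3600.0)


def full_mask_home_range(grid: GridSpec) -> HomeRange:
    """Home range whose isopleth mask covers the whole grid (toy helper)."""
    p = np.full((grid.nrows, grid.ncols), 1.0 / (grid.nrows * grid.ncols))
    ud = UtilizationDistribution(grid, p)
    return HomeRange(ud, 0.99, np.ones_like(p, dtype=bool))


def stack_from_array(data, cell_size=250.0, start=None):
    """ScaledStack from a [n_days, nrows, ncols] array of values in [0, 1]."""
    from datetime import date

    data = np.asarray(data, dtype=float)
    nd, nr, nc = data.shape
    grid = GridSpec(0.0, 0.0, cell_size, nc, nr)
    start = start or date(2020, 6, 1)
    dates = tuple(start + timedelta(days=i) for i in range(nd))
    return ScaledStack(grid, dates, data)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
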