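"""Telemetry cleaning, truncation and temporal binning.

The analysis unit downstream is animal x season x interval, where interval
is the whole season ("annual"), consecutive 30-day windows ("month30") or
consecutive 14-day windows ("biweek14") anchored at the season start.
Animals must be monitored for at least half of an interval to enter the
analysis, mirroring standard telemetry-screening practice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALES = ("annual", "month30", "biweek14")
NOMINAL_DAYS = {"month30": 30, "biweek14": 14}

__all__ = [
    "Trajectory",
    "IntervalWindow",
    "MonitoringRecord",
    "truncate_season",
    "filter_steps",
    "bin_trajectory",
    "monitoring_records",
    "apply_inclusion",
    "SCALES",
]


@dataclass(frozen=True)
class Trajectory:
    """Ordered, timestamped projected fixes for one animal.

    ``fixes`` has columns ``timestamp`` (tz-aware UTC), ``x`` and ``y``
    (projected meters).  Duplicate timestamps are dropped (keep first) with
    a warning; non-increasing timestamps raise.
    """

    animal_id: str
    fixes: pd.DataFrame
    site_id: str = ""

    def __post_init__(self) -> None:
        df = self.fixes
        required = {"timestamp", "x", "y"}
        if not required.issubset(df.columns):
            raise ValueError(f"fixes must have columns {required}")
        df = df.sort_values("timestamp").reset_index(drop=True)
        dup = df["timestamp"].duplicated()
        if dup.any():
            warnings.warn(
                f"{self.animal_id}: dropping {int(dup.sum())} duplicate timestamps"
            )
            df = df[~dup].reset_index(drop=True)
        if not np.isfinite(df[["x", "y"]].to_numpy(dtype=float)).all():
            raise ValueError(f"{self.animal_id}: non-finite coordinates")
        ts = df["timestamp"]
        if ts.dt.tz is None:
            df = df.assign(timestamp=ts.dt.tz_localize(timezone.utc))
        object.__setattr__(self, "fixes", df)

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def xy(self) -> np.ndarray:
        return self.fixes[["x", "y"]].to_numpy(dtype=float)

    @property
    def times_s(self) -> np.ndarray:
        """Timestamps as seconds since the first fix."""
        ts = self.fixes["timestamp"]
        return (ts - ts.iloc[0]).dt.total_seconds().to_numpy()

    def step_lengths(self) -> np.ndarray:
        d = np.diff(self.xy, axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, animal_id=None, site_id=""):
        if animal_id is None:
            animal_id = str(df["animal_id"].iloc[0])
        df = df.copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
        return cls(animal_id=animal_id, fixes=df[["timestamp", "x", "y"]], site_id=site_id)


@dataclass(frozen=True)
class IntervalWindow:
    """Half-open [start, end) date window at one temporal scale."""

    scale: str
    year: int
    index: int  # 1-based within the season
    start: date
    end: date
    nominal_days: int

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.end <= self.start:
            raise ValueError("end must be after start")

    @property
    def length_days(self) -> int:
        return (self.end - self.start).days

    @property
    def key(self) -> tuple:
        return (self.year, self.index)


@dataclass(frozen=True)
class MonitoringRecord:
    animal_id: str
    interval: IntervalWindow
    days_monitored: int
    fraction_monitored: float

    @property
    def included(self) -> bool:
        return self.fraction_monitored >= 0.5


def truncate_season(traj: Trajectory, season: tuple) -> Trajectory:
    """Retain fixes inside [season-start 00:00, season-end 00:00) each year.

    ``season`` is ((start_month, start_day), (end_month, end_day)).
    """
    (m0, d0), (m1, d1) = season
    ts = traj.fixes["timestamp"]
    keep = np.zeros(len(traj.fixes), dtype=bool)
    for year in ts.dt.year.unique():
        lo = datetime(int(year), m0, d0, tzinfo=timezone.utc)
        hi = datetime(int(year), m1, d1, tzinfo=timezone.utc)
        keep |= ((ts >= lo) & (ts < hi)).to_numpy()
    out = traj.fixes[keep].reset_index(drop=True)
    if out.empty:
        logger.info("%s: no fixes remain after season truncation", traj.animal_id)
    return replace(traj, fixes=out)


def filter_steps(traj: Trajectory, percentile: float = 95.0):
    """Drop fixes that terminate a step longer than the given percentile.

    The threshold is the linear-interpolation percentile of this
    animal-season's step lengths; removal is a single pass over the
    original steps (no recomputation after removals) and the first fix is
    never removed.  Returns (filtered trajectory, number removed).
    """
    if len(traj) < 2:
        warnings.warn(f"{traj.animal_id}: fewer than 2 fixes, step filter skipped")
        return traj, 0
    steps = traj.step_lengths()
    threshold = float(np.percentile(steps, percentile))
    drop = np.concatenate([[False], steps > threshold])
    out = traj.fixes[~drop].reset_index(drop=True)
    return replace(traj, fixes=out), int(drop.sum())


def season_windows(year: int, season: tuple, scale: str) -> list[IntervalWindow]:
    """Consecutive windows anchored at the season start for one year.

    A trailing partial window is kept only when it spans at least half of
    the nominal window length.
    """
    (m0, d0), (m1, d1) = season
    start, end = date(year, m0, d0), date(year, m1, d1)
    if scale == "annual":
        return [
            IntervalWindow("annual", year, 1, start, end, (end - start).days)
        ]
    nominal = NOMINAL_DAYS[scale]
    windows = []
    idx = 1
    cur = start
    while cur < end:
        nxt = min(cur + timedelta(days=nominal), end)
        length = (nxt - cur).days
        if length == nominal or length >= nominal / 2:
            windows.append(IntervalWindow(scale, year, idx, cur, nxt, nominal))
            idx += 1
        cur = nxt
    return windows


def bin_trajectory(traj: Trajectory, scale: str, season: tuple):
    """Partition a season-truncated trajectory into (window, sub-trajectory).

    Every retained fix falls in exactly one window; fixes in a dropped
    trailing remainder are not returned.
    """
    ts = traj.fixes["timestamp"]
    out = []
    for year in sorted(ts.dt.year.unique()):
        for win in season_windows(int(year), season, scale):
            lo = datetime.combine(win.start, datetime.min.time(), tzinfo=timezone.utc)
            hi = datetime.combine(win.end, datetime.min.time(), tzinfo=timezone.utc)
            sub = traj.fixes[(ts >= lo) & (ts < hi)].reset_index(drop=True)
            out.append((win, replace(traj, fixes=sub)))
    return out


def monitoring_records(traj: Trajectory, windows) -> list[MonitoringRecord]:
    """Coverage per window: fraction of window days holding >= 1 fix."""
    ts = traj.fixes["timestamp"]
    days = set(ts.dt.date)
    records = []
    for win in windows:
        n = sum(
            1
            for k in range((win.end - win.start).days)
            if (win.start + timedelta(days=k)) in days
        )
        frac = n / win.length_days
        records.append(MonitoringRecord(traj.animal_id, win, n, frac))
    return records


def apply_inclusion(records, threshold: float = 0.5):
    """Keep records monitored for at least `threshold` of the interval."""
    included, excluded = [], []
    for rec in records:
        if rec.fraction_monitored >= threshold:
            included.append(rec)
        else:
            excluded.append(rec)
            logger.info(
                "excluded %s %s: monitored %.3f < %.2f",
                rec.animal_id,
                rec.interval.key,
                rec.fraction_monitored,
                threshold,
            )
    return included
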