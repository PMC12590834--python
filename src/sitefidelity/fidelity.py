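"""Distance-based site fidelity across temporal scales.

Fidelity is measured inversely by mean minimum Euclidean distance between
the locations of a focal interval and those of the preceding interval.
Inter-annual distances restrict the comparison set to fixes of the prior
year whose day-of-year lies within +/- W days of the focal fix; a
sensitivity analysis over W = 5..100 days (step 5) with an explicit
asymptote rule replaces visual window selection.  Inter-month and
inter-week distances compare full consecutive intervals with no day
window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .tracks import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "FidelityRecord",
    "WindowSensitivityTable",
    "interannual_distance",
    "sequential_distance",
    "window_sensitivity",
    "select_window",
    "log_distance",
]

W_GRID_DEFAULT = tuple(range(5, 101, 5))


@dataclass(frozen=True)
class FidelityRecord:
    animal_id: str
    scale: str
    year: int
    index: int
    distance_m: float
    matched_fraction: float

    @property
    def log_distance(self) -> float:
        if self.distance_m <= 0:
            raise ValueError("log distance undefined for distance <= 0; see log_distance()")
        return float(np.log(self.distance_m))


@dataclass(frozen=True)
class WindowSensitivityTable:
    table: pd.DataFrame  # columns W, mean_distance_m, cv_distance
    selected_W: int


def log_distance(distances) -> np.ndarray:
    """ln(distance); falls back to ln(distance + 1 m) when zeros occur."""
    d = np.asarray(distances, dtype=float)
    if np.any(d == 0):
        logger.warning("zero fidelity distances present; using ln(distance + 1 m)")
        return np.log(d + 1.0)
    return np.log(d)


def _min_distances_windowed(focal: Trajectory, prev: Trajectory, window_days: float):
    """Per focal fix: min distance to prior-interval fixes within +/- W days of year."""
    f_xy = focal.xy
    p_xy = prev.xy
    f_doy = focal.fixes["timestamp"].dt.dayofyear.to_numpy()
    p_doy = prev.fixes["timestamp"].dt.dayofyear.to_numpy()
    mins = np.full(len(f_xy), np.nan)
    for doy in np.unique(f_doy):
        sel_p = np.abs(p_doy - doy) <= window_days
        if not sel_p.any():
            continue
        tree = cKDTree(p_xy[sel_p])
        sel_f = f_doy == doy
        mins[sel_f], _ = tree.query(f_xy[sel_f])
    return mins


def interannual_distance(
    track_t: Trajectory,
    track_prev: Trajectory,
    window_days: float,
    year: int | None = None,
) -> FidelityRecord | None:
    """Mean minimum distance from year-t fixes to windowed year t-1 fixes.

    Focal fixes with an empty comparison set are skipped (not imputed);
    ``matched_fraction`` reports the share retained.  Returns None when no
    focal fix has a comparison set.
    """
    if len(track_t) == 0 or len(track_prev) == 0:
        raise ValueError("both tracks must be nonempty")
    mins = _min_distances_windowed(track_t, track_prev, window_days)
    matched = np.isfinite(mins)
    if not matched.any():
        logger.warning("%s: no year-t fixes matched within W=%s days", track_t.animal_id, window_days)
        return None
    if year is None:
        year = int(track_t.fixes["timestamp"].dt.year.iloc[0])
    return FidelityRecord(
        animal_id=track_t.animal_id,
        scale="annual",
        year=year,
        index=1,
        distance_m=float(mins[matched].mean()),
        matched_fraction=float(matched.mean()),
    )


def sequential_distance(
    track_current: Trajectory,
    track_previous: Trajectory,
    scale: str = "month30",
    year: int = 0,
    index: int = 0,
) -> FidelityRecord | None:
    """Mean minimum distance between consecutive intervals, no day window."""
    if len(track_current) == 0 or len(track_previous) == 0:
        logger.warning("empty interval track; no fidelity record")
        return None
    tree = cKDTree(track_previous.xy)
    mins, _ = tree.query(track_current.xy)
    return FidelityRecord(
        animal_id=track_current.animal_id,
        scale=scale,
        year=year,
        index=index,
        distance_m=float(np.mean(mins)),
        matched_fraction=1.0,
    )


def window_sensitivity(
    year_pairs,
    w_grid=W_GRID_DEFAULT,
    tol: float = 0.02,
    plot_path=None,
) -> WindowSensitivityTable:
    """Mean and CV of inter-annual distance across individuals per window W.

    ``year_pairs`` is an iterable of (track_t, track_prev).  The CV is the
    between-individual sd/mean of the per-individual distances.
    """
    pairs = list(year_pairs)
    if len(pairs) < 2:
        raise ValueError("window sensitivity needs >= 2 animal-year pairs")
    rows = []
    for W in w_grid:
        dists = []
        for track_t, track_prev in pairs:
            rec = interannual_distance(track_t, track_prev, W)
            if rec is not None:
                dists.append(rec.distance_m)
        dists = np.asarray(dists)
        mean = float(dists.mean())
        cv = float(dists.std(ddof=1) / mean) if mean > 0 and len(dists) > 1 else 0.0
        rows.append({"W": int(W), "mean_distance_m": mean, "cv_distance": cv})
    table = pd.DataFrame(rows)
    selected = select_window(table, tol=tol)
    result = WindowSensitivityTable(table=table, selected_W=selected)
    if plot_path is not None:
        _plot_sensitivity(result, plot_path)
    return result


def select_window(table, tol: float = 0.02) -> int:
    """Smallest W whose next two grid steps change mean and CV by < tol.

    A reproducible stand-in for visual asymptote identification; if no W
    qualifies the largest grid value is returned with a warning.
    """
    df = table.table if isinstance(table, WindowSensitivityTable) else table
    df = df.sort_values("W").reset_index(drop=True)
    W = df["W"].to_numpy()

    def rel_change(series):
        s = series.to_numpy(dtype=float)
        denom = np.where(np.abs(s[:-1]) > 0, np.abs(s[:-1]), 1.0)
        return np.abs(np.diff(s)) / denom

    rc_mean = rel_change(df["mean_distance_m"])
    rc_cv = rel_change(df["cv_distance"])
    for i in range(len(W) - 2):
        if (
            rc_mean[i] < tol
            and rc_mean[i + 1] < tol
            and rc_cv[i] < tol
            and rc_cv[i + 1] < tol
        ):
            return int(W[i])
    logger.warning("no asymptote found; falling back to largest window %s", W[-1])
    return int(W[-1])


def _plot_sensitivity(result: WindowSensitivityTable, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    df = result.table
    axes[0].plot(df["W"], df["mean_distance_m"], marker="o")
    axes[0].set_xlabel("window size W (days)")
    axes[0].set_ylabel("mean inter-annual distance (m)")
    axes[1].plot(df["W"], df["cv_distance"], marker="o", color="tab:orange")
    axes[1].set_xlabel("window size W (days)")
    axes[1].set_ylabel("CV of inter-annual distance")
    for ax in axes:
        ax.axvline(result.selected_W, color="grey", ls="--", lw=1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
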