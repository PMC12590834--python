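"""Plain-text readers and writers for the pipeline's file formats.

Telemetry, neonate and condition tables are CSV; daily biomass layers are
ESRI ASCII grids (`biomass_YYYY-MM-DD.asc`); isopleth outlines are
GeoJSON; the simulation truth record is JSON.
"""

from __future__ import annotations

import json
import re
from datetime import date, datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GridSpec
from .dbbmm import HomeRange
from .foodscape import FoodscapeStack
from .recruitment import NeonateRecord
from .tracks import Trajectory

__all__ = [
    "write_telemetry",
    "read_telemetry",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_foodscape",
    "read_foodscape",
    "write_neonates",
    "read_neonates",
    "write_truth",
    "home_range_geojson",
    "write_dataset",
]


def write_telemetry(trajectories, path) -> None:
    frames = []
    for tr in trajectories:
        df = tr.fixes.copy()
        df.insert(0, "animal_id", tr.animal_id)
        if tr.site_id:
            df["site_id"] = tr.site_id
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False, float_format="%.3f")


def read_telemetry(path) -> list[Trajectory]:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    out = []
    for animal_id, sub in df.groupby("animal_id", sort=True):
        site = str(sub["site_id"].iloc[0]) if "site_id" in sub else ""
        out.append(
            Trajectory(
                animal_id=str(animal_id),
                fixes=sub[["timestamp", "x", "y"]].reset_index(drop=True),
                site_id=site,
            )
        )
    return out


def write_ascii_grid(grid: GridSpec, values: np.ndarray, path) -> None:
    """ESRI ASCII grid; data rows run north to south."""
    header = (
        f"ncols {grid.ncols}\nnrows {grid.nrows}\n"
        f"xllcorner {grid.x0:.3f}\nyllcorner {grid.y0:.3f}\n"
        f"cellsize {grid.cell_size:.3f}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values[::-1], fmt="%.6f")


def read_ascii_grid(path):
    with open(path) as fh:
        head = {}
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        values = np.loadtxt(fh)
    grid = GridSpec(
        x0=head["xllcorner"],
        y0=head["yllcorner"],
        cell_size=head["cellsize"],
        ncols=int(head["ncols"]),
        nrows=int(head["nrows"]),
    )
    return grid, np.atleast_2d(values)[::-1]


def write_foodscape(stack: FoodscapeStack, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for day, layer in zip(stack.dates, stack.data):
        write_ascii_grid(stack.grid, layer, outdir / f"biomass_{day.isoformat()}.asc")


def read_foodscape(indir) -> FoodscapeStack:
    indir = Path(indir)
    pat = re.compile(r"biomass_(\d{4}-\d{2}-\d{2})\.asc$")
    entries = []
    for p in sorted(indir.iterdir()):
        m = pat.search(p.name)
        if m:
            entries.append((date.fromisoformat(m.group(1)), p))
    if not entries:
        raise FileNotFoundError(f"no biomass_YYYY-MM-DD.asc layers in {indir}")
    entries.sort()
    grid = None
    layers, days = [], []
    for day, p in entries:
        g, vals = read_ascii_grid(p)
        grid = grid or g
        if g != grid:
            raise ValueError(f"{p}: grid differs from first layer")
        layers.append(vals)
        days.append(day)
    return FoodscapeStack(grid, tuple(days), np.stack(layers))


def write_neonates(records, path) -> None:
    pd.DataFrame(
        [
            {
                "mother_id": r.mother_id,
                "year": r.year,
                "birth_date": r.birth_date.isoformat(),
                "end_date": r.end_date.isoformat(),
                "fate": r.fate,
                "maternal_fidelity_z": r.maternal_fidelity_z,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_neonates(path) -> list[NeonateRecord]:
    df = pd.read_csv(path)
    return [
        NeonateRecord(
            mother_id=str(r.mother_id),
            year=int(r.year),
            birth_date=date.fromisoformat(r.birth_date),
            end_date=date.fromisoformat(r.end_date),
            fate=str(r.fate),
            maternal_fidelity_z=float(getattr(r, "maternal_fidelity_z", 0.0)),
        )
        for r in df.itertuples()
    ]


def _json_default(obj):
    if isinstance(obj, (date, datetime)):
        return obj.isoformat()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=_json_default, sort_keys=True)


def home_range_geojson(hr: HomeRange, path=None) -> dict:
    """Isopleth mask as a (multi)polygon of unioned grid cells."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    g = hr.ud.grid
    cells = [
        box(
            g.x0 + c * g.cell_size,
            g.y0 + r * g.cell_size,
            g.x0 + (c + 1) * g.cell_size,
            g.y0 + (r + 1) * g.cell_size,
        )
        for r, c in zip(*np.nonzero(hr.mask))
    ]
    geom = unary_union(cells)
    feature = {
        "type": "Feature",
        "properties": {
            "isopleth_level": hr.isopleth_level,
            "area_km2": hr.area_km2,
        },
        "geometry": mapping(geom),
    }
    doc = {"type": "FeatureCollection", "features": [feature]}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, default=_json_default)
    return doc


def write_dataset(dataset, outdir) -> None:
    """Serialize a SyntheticDataset: telemetry, rasters, neonates, condition, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_telemetry(dataset.trajectories, outdir / "telemetry.csv")
    write_foodscape(dataset.foodscape, outdir / "foodscape")
    write_neonates(dataset.neonates, outdir / "neonates.csv")
    dataset.condition.to_csv(outdir / "condition.csv", index=False, float_format="%.6f")
    write_truth(dataset.truth, outdir / "truth.json")
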