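"""Occurrence ingestion, grid deduplication, and protection overlay.

Presence records arrive as point tables (CSV with ``id,x,y,source`` columns
or GeoJSON points). Before modelling they are thinned to at most one record
per grid cell — the cell centroid stands in for all records in that cell —
which removes the density bias of opportunistic sampling. Conservation
status is summarized by overlaying points on protected-area polygons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape
from shapely.prepared import prep

from .raster import CRSError, RasterGrid

log = logging.getLogger(__name__)

POINT_COLUMNS = ["id", "x", "y", "source"]


@dataclass
class OccurrenceSet:
    """Presence points with coordinates and provenance tags.

    ``points`` is a DataFrame with columns ``id, x, y, source``. After
    gridding (``gridded=True``) no two points share a grid cell.
    """

    points: pd.DataFrame
    crs: str = "EPSG:32632"
    gridded: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in POINT_COLUMNS if c not in self.points.columns]
        if missing:
            raise ValueError(f"points table missing columns {missing}")
        xy = self.points[["x", "y"]].to_numpy(float)
        if xy.size and not np.all(np.isfinite(xy)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.points["x"].to_numpy(float),
                self.points["y"].to_numpy(float))

    # -- I/O ---------------------------------------------------------------
    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.points.to_csv(path, index=False)
        return path

    @classmethod
    def read_csv(cls, path: str | Path, crs: str = "EPSG:32632",
                 gridded: bool = False) -> "OccurrenceSet":
        df = pd.read_csv(path)
        if "id" not in df.columns:
            df.insert(0, "id", [f"r{i}" for i in range(len(df))])
        if "source" not in df.columns:
            df["source"] = "unknown"
        return cls(points=df[POINT_COLUMNS], crs=crs, gridded=gridded)

    @classmethod
    def read_geojson(cls, path: str | Path,
                     crs: str = "EPSG:32632") -> "OccurrenceSet":
        gj = json.loads(Path(path).read_text())
        feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
        rows = []
        for i, f in enumerate(feats):
            geom = f.get("geometry", f)
            if geom["type"] != "Point":
                continue
            x, y = geom["coordinates"][:2]
            props = f.get("properties") or {}
            rows.append({
                "id": str(props.get("id", f"g{i}")),
                "x": float(x), "y": float(y),
                "source": str(props.get("source", "geojson")),
            })
        return cls(points=pd.DataFrame(rows, columns=POINT_COLUMNS), crs=crs)


def dedup_to_grid(occ: OccurrenceSet, grid: RasterGrid) -> OccurrenceSet:
    """Thin occurrences to one representative point per occupied grid cell.

    Exact duplicate records (same coordinates and source) are collapsed
    first; then every occupied cell contributes a single point located at
    the cell centroid. Points outside the grid extent are dropped (the
    count is logged). Cell membership follows the half-open convention of
    :meth:`RasterGrid.cell_of`, so edge points are assigned unambiguously.

    Idempotent: re-gridding a gridded set returns the same set.
    """
    if occ.crs != grid.crs:
        raise CRSError(
            f"occurrences in {occ.crs!r} but grid in {grid.crs!r}; "
            "reproject before gridding")
    pts = occ.points.drop_duplicates(subset=["x", "y", "source"])
    if len(pts) == 0:
        return OccurrenceSet(points=pts.copy(), crs=occ.crs, gridded=True)
    x = pts["x"].to_numpy(float)
    y = pts["y"].to_numpy(float)
    row, col = grid.cell_of(x, y)
    inside = grid.contains(row, col)
    n_dropped = int((~inside).sum())
    if n_dropped:
        log.info("dedup_to_grid: dropped %d points outside the grid",
                 n_dropped)
    row, col = row[inside], col[inside]
    cells = pd.DataFrame({"row": row, "col": col,
                          "source": pts["source"].to_numpy()[inside]})
    grouped = cells.groupby(["row", "col"], sort=True)["source"].first()
    rows = grouped.index.get_level_values("row").to_numpy()
    cols = grouped.index.get_level_values("col").to_numpy()
    cx, cy = grid.centroid(rows, cols)
    out = pd.DataFrame({
        "id": [f"c{r}_{c}" for r, c in zip(rows, cols)],
        "x": cx, "y": cy,
        "source": grouped.to_numpy(),
    })
    return OccurrenceSet(points=out.reset_index(drop=True), crs=occ.crs,
                         gridded=True)


@dataclass
class ProtectionSummary:
    """Per-group protection counts with rounded percentages.

    ``table`` columns: group, n_total, n_unprotected, pct_unprotected
    (integer-rounded percentage of records outside every polygon).
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def overall(self) -> pd.Series:
        return self.table.loc[self.table["group"] == "Overall"].iloc[0]

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def read_polygons_geojson(path: str | Path) -> list:
    """Load (multi)polygons from a GeoJSON file, repairing invalid rings."""
    gj = json.loads(Path(path).read_text())
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    polys = []
    for f in feats:
        geom = shape(f.get("geometry", f))
        if geom.is_empty:
            continue
        if not geom.is_valid:
            geom = geom.buffer(0)
        polys.append(geom)
    return polys


def protection_summary(
    occ: OccurrenceSet,
    protected_polygons: Sequence,
    groups: Sequence[str] | None = None,
) -> ProtectionSummary:
    """Count how many records fall outside every protected-area polygon.

    A point on a polygon boundary counts as protected (inclusive
    containment — conservative for conservation accounting). ``groups``
    assigns one label per point (e.g. region); an "Overall" row is always
    appended. With an empty polygon set every point is unprotected.
    """
    x, y = occ.xy
    n = len(occ)
    protected = np.zeros(n, dtype=bool)
    prepared = [prep(p) for p in protected_polygons]
    for i in range(n):
        pt = Point(x[i], y[i])
        protected[i] = any(p.intersects(pt) for p in prepared)
    labels = (np.asarray(list(groups), dtype=object) if groups is not None
              else np.asarray(["all"] * n, dtype=object))
    if len(labels) != n:
        raise ValueError("groups must give one label per point")
    rows = []
    for g in pd.unique(labels):
        sel = labels == g
        tot = int(sel.sum())
        unprot = int((~protected[sel]).sum())
        rows.append({"group": g, "n_total": tot, "n_unprotected": unprot,
                     "pct_unprotected": unprotected_pct(unprot, tot)})
    rows.append({
        "group": "Overall", "n_total": n,
        "n_unprotected": int((~protected).sum()),
        "pct_unprotected": unprotected_pct(int((~protected).sum()), n),
    })
    return ProtectionSummary(table=pd.DataFrame(rows))


def unprotected_pct(n_unprotected: int, n_total: int) -> int:
    """Integer-rounded percentage of unprotected records."""
    if not 0 <= n_unprotected <= n_total:
        raise ValueError("need 0 <= n_unprotected <= n_total")
    if n_total == 0:
        return 0
    return int(round(100.0 * n_unprotected / n_total))
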