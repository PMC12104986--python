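"""Threshold derivation, suitability classification, scenario projection
and extrapolation diagnostics.

Suitability maps are cut into classes using three thresholds derived from
predictions at the training presences: the minimum training presence
(MTP, the lowest predicted value at any training record), the 10th
percentile training presence (P10), and the fixed cloglog anchor
1 - 1/e ~ 0.632 (the value of a cell expected to hold one individual).
Future-scenario stacks are predicted with clamping, binarized at the
fixed threshold, and summarized as area change and the altitude
distribution of high-suitability cells.

The multivariate environmental similarity surface (MESS) flags novel
conditions: per variable, a percentile-based similarity score that is
negative outside the training range; the surface is the minimum over
variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import EnvStack, GeometryError, RasterGrid

log = logging.getLogger(__name__)

FIXED_THRESHOLD = 1.0 - 1.0 / np.e

CLASS_NAMES = ("High", "Moderate", "Low", "Negligible")


@dataclass
class ThresholdSet:
    """MTP / P10 / fixed suitability thresholds."""

    mtp: float
    p10: float
    fixed: float = FIXED_THRESHOLD

    def __post_init__(self) -> None:
        if not (0.0 <= self.mtp <= self.p10 <= 1.0):
            raise ValueError(
                f"need 0 <= mtp ({self.mtp}) <= p10 ({self.p10}) <= 1")
        if self.p10 > self.fixed:
            log.warning("P10 (%.4f) exceeds the fixed threshold (%.4f)",
                        self.p10, self.fixed)


def compute_thresholds(pred_at_presences) -> ThresholdSet:
    """Derive thresholds from predictions at the training presences.

    MTP is the minimum; P10 the 10th percentile by linear interpolation
    between order statistics. Fewer than 10 predictions make P10 shaky
    (warned, not fatal).
    """
    p = np.asarray(pred_at_presences, float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no presence predictions supplied")
    if p.size < 10:
        log.warning("P10 from only %d predictions is unreliable", p.size)
    return ThresholdSet(
        mtp=float(p.min()),
        p10=float(np.quantile(p, 0.10, method="linear")),
    )


@dataclass
class ClassifiedMap:
    """A classified suitability raster with an area accounting table.

    ``classes`` holds integer codes (4-class scheme: 3=High, 2=Moderate,
    1=Low, 0=Negligible; binary: 1=High, 0=Low). ``area_table`` columns:
    class, km2, pct (percentage of the study-area extent = all non-nodata
    cells).
    """

    classes: RasterGrid
    thresholds: ThresholdSet
    scheme: str
    area_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def area_km2(self, name: str) -> float:
        row = self.area_table.loc[self.area_table["class"] == name]
        return float(row["km2"].iloc[0]) if len(row) else 0.0

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.area_table.to_csv(path, index=False)
        return path


def classify_map(
    suitability: RasterGrid,
    thresholds: ThresholdSet,
    scheme: str = "four-class",
) -> ClassifiedMap:
    """Cut a suitability raster into discrete classes with area accounting.

    Four-class: High = (fixed, 1]; Moderate = (p10, fixed]; Low =
    (mtp, p10]; Negligible = [0, mtp]. A cell exactly at a threshold joins
    the lower class. Binary: High = (fixed, 1], Low otherwise. Class areas
    (cell count x cell area) always sum to the non-nodata extent;
    percentages are taken against that extent.
    """
    t = thresholds
    vals = suitability.values
    ok = np.isfinite(vals)
    if ok.any() and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9):
        raise ValueError("suitability must lie in [0, 1]")
    out = np.full(suitability.shape, suitability.nodata)
    if scheme == "four-class":
        code = np.select(
            [vals > t.fixed, vals > t.p10, vals > t.mtp],
            [3, 2, 1], default=0).astype(float)
        labels = {3: "High", 2: "Moderate", 1: "Low", 0: "Negligible"}
    elif scheme == "binary":
        code = (vals > t.fixed).astype(float)
        labels = {1: "High", 0: "Low"}
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    out[ok] = code[ok]
    grid = suitability.copy_with(out)
    cell = suitability.cell_area_km2
    total = float(ok.sum()) * cell
    rows = []
    for c in sorted(labels, reverse=True):
        n = int(np.sum(out[ok] == c))
        rows.append({"class": labels[c], "km2": n * cell,
                     "pct": 100.0 * n * cell / total if total else 0.0})
    return ClassifiedMap(classes=grid, thresholds=t, scheme=scheme,
                         area_table=pd.DataFrame(rows))


def percent_change(present_km2: float, future_km2: float) -> float:
    """Signed percent change of area relative to the present extent."""
    if present_km2 <= 0:
        raise ValueError("present area must be positive")
    return 100.0 * (future_km2 - present_km2) / present_km2


@dataclass
class ScenarioResult:
    """One (scenario, period) projection with change statistics."""

    scenario: str
    period: str
    suitability: RasterGrid
    binary: ClassifiedMap
    high_km2: float
    percent_change: float
    altitude_summary: pd.Series | None = None

    def row(self) -> dict:
        d = {
            "scenario": self.scenario, "period": self.period,
            "high_km2": self.high_km2, "percent_change": self.percent_change,
        }
        if self.altitude_summary is not None:
            d.update({f"alt_{k}": v for k, v in
                      self.altitude_summary.items()})
        return d


def altitude_summary(classes: RasterGrid, dem: RasterGrid,
                     high_code: float = 1.0) -> pd.Series:
    """Elevation distribution (min/quartiles/median/max) of High cells."""
    if not classes.same_geometry(dem):
        raise GeometryError("DEM geometry must match the classified map")
    sel = (classes.values == high_code) & ~dem.mask
    alts = dem.values[sel]
    if alts.size == 0:
        return pd.Series({"min": np.nan, "q25": np.nan, "median": np.nan,
                          "q75": np.nan, "max": np.nan, "n_cells": 0})
    return pd.Series({
        "min": float(alts.min()),
        "q25": float(np.quantile(alts, 0.25)),
        "median": float(np.median(alts)),
        "q75": float(np.quantile(alts, 0.75)),
        "max": float(alts.max()),
        "n_cells": int(alts.size),
    })


def project_scenario(
    results,
    future_stack: EnvStack,
    scenario: str,
    period: str,
    present: ClassifiedMap,
    dem: RasterGrid | None = None,
) -> ScenarioResult:
    """Project a fitted model onto a future stack and summarize the change.

    Prediction uses cloglog output with clamping (transfers beyond the
    training range are pinned to it); cells are binarized at the fixed
    threshold; the high-suitability area is compared with the present map
    and, if a DEM is given, the altitude distribution of High cells is
    summarized.
    """
    if not future_stack.grid.same_geometry(present.classes):
        raise GeometryError("future stack not aligned with the present map")
    suit = results.predict_stack(future_stack, mode="cloglog", clamp=True)
    binary = classify_map(suit, present.thresholds, scheme="binary")
    high = binary.area_km2("High")
    present_high = (present.area_km2("High") if present.scheme == "binary"
                    else present.area_km2("High"))
    alt = altitude_summary(binary.classes, dem) if dem is not None else None
    return ScenarioResult(
        scenario=scenario, period=period, suitability=suit, binary=binary,
        high_km2=high,
        percent_change=percent_change(present_high, high),
        altitude_summary=alt,
    )


def mess_scores(reference: pd.DataFrame, query: pd.DataFrame) -> np.ndarray:
    """Multivariate environmental similarity of query points (vectorized).

    Per variable, with ``f`` the percentage of reference values strictly
    below the query value v:

    * f = 0:       s = 100 * (v - min) / (max - min)
    * 0 < f <= 50: s = 2 f
    * 50 < f < 100: s = 2 (100 - f)
    * f = 100:     s = 100 * (max - v) / (max - min)

    The MESS value is the minimum over variables; negative values flag
    conditions outside the training envelope. Constant reference
    variables are excluded with a warning.
    """
    cols = []
    for c in reference.columns:
        ref = np.sort(reference[c].to_numpy(float))
        ref = ref[np.isfinite(ref)]
        if ref.size == 0 or ref[0] == ref[-1]:
            log.warning("MESS: variable %r has a degenerate reference; "
                        "excluded", c)
            continue
        if c not in query.columns:
            raise KeyError(f"query is missing variable {c!r}")
        v = query[c].to_numpy(float)
        n = ref.size
        lo, hi = ref[0], ref[-1]
        f = 100.0 * np.searchsorted(ref, v, side="left") / n
        s = np.where(
            f == 0.0, 100.0 * (v - lo) / (hi - lo),
            np.where(
                f <= 50.0, 2.0 * f,
                np.where(f < 100.0, 2.0 * (100.0 - f),
                         100.0 * (hi - v) / (hi - lo))))
        cols.append(s)
    if not cols:
        raise ValueError("no usable reference variables for MESS")
    return np.min(np.column_stack(cols), axis=1)


def mess(reference: pd.DataFrame, query_stack: EnvStack,
         variables: list[str] | None = None) -> RasterGrid:
    """MESS raster of a query stack against training reference samples."""
    variables = variables if variables is not None else [
        c for c in reference.columns if c in query_stack.continuous]
    table, rows, cols = query_stack.table(variables)
    scores = mess_scores(reference[variables], table)
    out = np.full(query_stack.grid.shape, query_stack.grid.nodata)
    out[rows, cols] = scores
    return query_stack.grid.copy_with(out)
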