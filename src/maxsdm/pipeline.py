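"""End-to-end pipeline: occurrences -> selection -> tuning -> final fit
-> thresholds/classification -> scenario projection -> MESS.

The pipeline is configured by a single YAML file (see
:class:`PipelineConfig`) and writes every intermediate table and raster
into a run directory, together with a machine-readable manifest of seeds
and parameters, so a rerun with the same config is bit-identical.

``make_demo`` writes a small self-contained virtual-species dataset (grid,
layers, occurrences, one future scenario and a config) used by the docs
and the test suite.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import evaluate, project, synth
from .env import correlation_select, sample_cells
from .model import MaxEnt, sample_background
from .occ import OccurrenceSet, dedup_to_grid
from .raster import CATEGORICAL, EnvStack, RasterGrid

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline configuration is invalid or references missing paths."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Mirrors the YAML layout; every path is resolved relative to the config
    file. Seeds are explicit integers so full runs are reproducible.
    """

    occurrences: Path
    layers_dir: Path
    out_dir: Path
    dem: str | None = None
    scenarios: list[dict] = field(default_factory=list)
    corr_threshold: float = 0.7
    priority: list[str] = field(default_factory=list)
    vif_limit: float = 5.0
    classes_grid: list[str] = field(
        default_factory=lambda: list(evaluate.DEFAULT_CLASS_GRID))
    mult_grid: list[float] = field(
        default_factory=lambda: [float(m) for m in evaluate.DEFAULT_MULT_GRID])
    family: str | None = None
    n_background: int = 20_000
    cv_k: int = 4
    n_knots: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        try:
            raw: dict[str, Any] = yaml.safe_load(path.read_text())
        except Exception as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        base = path.parent
        try:
            cfg = cls(
                occurrences=base / raw["occurrences"],
                layers_dir=base / raw["layers_dir"],
                out_dir=base / raw.get("out_dir", "run"),
                dem=raw.get("dem"),
                scenarios=raw.get("scenarios", []),
                corr_threshold=float(raw.get("corr_threshold", 0.7)),
                priority=list(raw.get("priority", [])),
                vif_limit=float(raw.get("vif_limit", 5.0)),
                classes_grid=list(raw.get(
                    "classes_grid", evaluate.DEFAULT_CLASS_GRID)),
                mult_grid=[float(m) for m in raw.get(
                    "mult_grid", evaluate.DEFAULT_MULT_GRID)],
                family=raw.get("family"),
                n_background=int(raw.get("n_background", 20_000)),
                cv_k=int(raw.get("cv_k", 4)),
                n_knots=int(raw.get("n_knots", 50)),
                seed=int(raw.get("seed", 0)),
            )
        except KeyError as exc:
            raise ConfigError(f"config missing required key {exc}") from exc
        for p, what in [(cfg.occurrences, "occurrences"),
                        (cfg.layers_dir, "layers_dir")]:
            if not Path(p).exists():
                raise ConfigError(f"{what} path does not exist: {p}")
        for sc in cfg.scenarios:
            sp = base / sc["layers_dir"]
            if not sp.exists():
                raise ConfigError(f"scenario layers missing: {sp}")
            sc["layers_dir"] = str(sp)
        if cfg.dem is not None:
            cfg.dem = str(base / cfg.dem)
            if not Path(cfg.dem).exists():
                raise ConfigError(f"DEM path does not exist: {cfg.dem}")
        return cfg


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-14s %.2fs", name, t1 - t0)
    return t1


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow; returns the run directory.

    Stages: occurrence gridding -> collinearity selection -> tuning grid
    -> final fit -> thresholds and four-class map -> scenario projections
    -> MESS. Every stage writes its artifacts before the next one runs, so
    a failure leaves the completed trail in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    stack = EnvStack.read(config.layers_dir)
    occ = OccurrenceSet.read_csv(config.occurrences, crs=stack.grid.crs)
    occ = dedup_to_grid(occ, stack.grid)
    occ.write_csv(out / "occurrences_gridded.csv")
    t0 = _stage("occ", t0)

    report = correlation_select(
        stack, threshold=config.corr_threshold, priority=config.priority,
        seed=config.seed)
    report.write(out / "selection")
    stack_sel = stack.subset(report.kept)
    t0 = _stage("select", t0)

    x, y = occ.xy
    presence = stack_sel.extract(x, y).dropna()
    keep_idx = stack_sel.extract(x, y).dropna().index.to_numpy()
    px, py = x[keep_idx], y[keep_idx]
    background = sample_background(stack_sel, config.n_background,
                                   seed=config.seed)
    bx, by = background["x"].to_numpy(), background["y"].to_numpy()

    table, selected = evaluate.tune_and_select(
        presence, background, (px, py), (bx, by),
        classes_grid=config.classes_grid, mult_grid=config.mult_grid,
        k=config.cv_k, categorical=stack_sel.categorical,
        n_knots=config.n_knots, family=config.family)
    table.to_csv(out / "tuning.csv", index=False)
    t0 = _stage("tune", t0)

    results = MaxEnt(
        presence, background, classes=selected["classes"],
        reg_mult=selected["reg_mult"], categorical=stack_sel.categorical,
        n_knots=config.n_knots).fit()
    results.to_json(out / "model.json")
    (out / "summary.txt").write_text(results.summary())
    importance = results.variable_importance(seed=config.seed)
    importance.to_csv(out / "importance.csv", index=False)
    curves = []
    for v in results.variables:
        c = results.response_curve(v)
        c.insert(0, "variable", v)
        curves.append(c)
    pd.concat(curves, ignore_index=True).to_csv(
        out / "response_curves.csv", index=False)
    t0 = _stage("fit", t0)

    pred_at_presence = results.predict(presence, mode="cloglog")
    thresholds = project.compute_thresholds(pred_at_presence)
    suit = results.predict_stack(stack_sel, mode="cloglog")
    suit.write_ascii(out / "suitability.asc")
    present4 = project.classify_map(suit, thresholds, scheme="four-class")
    present4.classes.write_ascii(out / "classes.asc")
    present4.write_csv(out / "areas_present.csv")
    present_bin = project.classify_map(suit, thresholds, scheme="binary")
    t0 = _stage("classify", t0)

    dem = RasterGrid.read_ascii(config.dem) if config.dem else None
    scen_rows = []
    train_ref = background[stack_sel.continuous]
    for sc in config.scenarios:
        fut = EnvStack.read(sc["layers_dir"]).subset(report.kept)
        res = project.project_scenario(
            results, fut, scenario=sc.get("label", "scenario"),
            period=str(sc.get("period", "")), present=present_bin, dem=dem)
        res.suitability.write_ascii(
            out / f"suitability_{res.scenario}_{res.period}.asc")
        res.binary.classes.write_ascii(
            out / f"binary_{res.scenario}_{res.period}.asc")
        scen_rows.append(res.row())
        m = project.mess(train_ref, fut)
        m.write_ascii(out / f"mess_{res.scenario}_{res.period}.asc")
    if scen_rows:
        pd.DataFrame(scen_rows).to_csv(out / "scenarios.csv", index=False)
    t0 = _stage("project", t0)

    manifest = {
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in vars(config).items()},
        "selected": {k: (v if not isinstance(v, float) or np.isfinite(v)
                         else None) for k, v in selected.items()},
        "thresholds": {"mtp": thresholds.mtp, "p10": thresholds.p10,
                       "fixed": thresholds.fixed},
        "n_presence": int(len(presence)),
        "n_background": int(len(background)),
    }
    blob = json.dumps(manifest, sort_keys=True, default=str)
    manifest["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return out


def make_demo(directory: str | Path, seed: int = 0,
              size: int = 64, n_presences: int = 300) -> Path:
    """Write a small virtual-species demo dataset and pipeline config.

    A ``size x size`` 1-km grid with 8 smooth continuous layers (two
    highly correlated pairs, so collinearity screening has work to do), a
    4-class soil layer, a DEM, presences sampled from a two-variable
    unimodal truth with soil preferences, and one warming "future"
    scenario shifting the climate layer means.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid = RasterGrid(np.zeros((size, size)), x0=600_000.0, y0=4_800_000.0,
                      dx=1000.0, dy=1000.0, crs="EPSG:32632")
    names = ["bio4", "bio15", "bio12", "bio9", "bio8", "bio3", "slope",
             "aspect"]
    corr = np.eye(8)
    # two collinear pairs: bio4~bio9 and bio12~bio8
    for i, j, r in [(0, 3, 0.85), (2, 4, 0.8)]:
        corr[i, j] = corr[j, i] = r
    means = [635.0, 45.0, 900.0, 12.0, 15.0, 40.0, 8.0, 180.0]
    sds = [80.0, 12.0, 250.0, 4.0, 4.0, 6.0, 5.0, 90.0]
    stack = synth.generate_env_stack(
        grid, n_continuous=8, target_corr=corr, n_classes=4,
        smoothness=6.0, seed=seed, names=names, means=means, sds=sds)
    truth = synth.true_suitability(
        stack, synth.default_truth_responses(),
        intercept=synth.DEFAULT_TRUTH_INTERCEPT)
    occ = synth.sample_presences(truth, n=n_presences, seed=seed + 1)

    layers_dir = directory / "layers"
    stack.write(layers_dir)
    truth.suitability.write_ascii(directory / "true_suitability.asc")
    occ.write_csv(directory / "occurrences.csv")
    dem_field = synth._smooth_unit_field(grid.shape, 8.0,
                                         np.random.default_rng(seed + 2))
    dem = grid.copy_with(500.0 + 300.0 * dem_field)
    dem.write_ascii(directory / "dem.asc")

    # Severe warming-and-drying shift (~1.5 sd on the truth's climate
    # drivers) so the virtual species' envelope genuinely contracts.
    future = synth.shift_future(stack, {
        "bio4": 120.0, "bio15": 18.0, "bio12": -250.0, "bio9": 4.0,
        "bio8": 3.0, "bio3": 3.0})
    future.write(directory / "layers_future")

    config = {
        "occurrences": "occurrences.csv",
        "layers_dir": "layers",
        "out_dir": "run",
        "dem": "dem.asc",
        "scenarios": [
            {"label": "SSP5-like", "period": "2071-2100",
             "layers_dir": "layers_future"},
        ],
        "corr_threshold": 0.7,
        "priority": ["bio4", "bio15", "bio12"],
        "n_background": min(2000, size * size),
        "cv_k": 4,
        "n_knots": 8,
        "seed": seed,
    }
    (directory / "config.yaml").write_text(yaml.safe_dump(config))
    return directory
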