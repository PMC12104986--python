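"""Predictor harmonization and collinearity-driven variable selection.

Heterogeneous source rasters are resampled onto the study grid (bilinear
for continuous layers, nearest-neighbour for categorical ones). The
predictor set is then pruned by an iterative Pearson procedure: while any
pair of continuous variables correlates above the threshold, the variable
with the highest mean absolute correlation to the remaining ones is
removed — unless it is on the priority list, in which case its partners
are removed instead. Variance inflation factors verify the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import CATEGORICAL, CONTINUOUS, EnvStack, RasterGrid

log = logging.getLogger(__name__)


class IrreducibleConflictError(ValueError):
    """Two priority variables violate the correlation threshold mutually."""


def resample_to_grid(source: RasterGrid, target: RasterGrid,
                     kind: str = CONTINUOUS) -> RasterGrid:
    """Resample one raster onto the target geometry.

    Continuous layers use bilinear interpolation at target cell centers;
    categorical layers use nearest neighbour. Target cells whose center
    falls outside the source extent, or whose interpolation touches a
    source nodata cell, become nodata.
    """
    if source.crs != target.crs:
        from .raster import CRSError

        raise CRSError(
            f"source CRS {source.crs!r} != target CRS {target.crs!r}")
    tx, ty = target.cell_centers()
    # Fractional source indices of the target cell centers (cell-center
    # registration: index i sits at coordinate of the cell midpoint).
    col_f = (tx - source.x0) / source.dx - 0.5
    row_f = (source.y0 - ty) / source.dy - 0.5
    nr, nc = source.shape
    src = source.data.astype(float)
    bad = source.mask
    src_f = np.where(bad, np.nan, src)
    order = 1 if kind == CONTINUOUS else 0
    out = ndimage.map_coordinates(
        src_f, [row_f, col_f], order=order, mode="constant", cval=np.nan)
    outside = ((col_f < -0.5) | (col_f > nc - 0.5)
               | (row_f < -0.5) | (row_f > nr - 0.5))
    # Allow edge cells (within half a cell of the border) by clamping.
    col_c = np.clip(col_f, 0, nc - 1)
    row_c = np.clip(row_f, 0, nr - 1)
    edge = ~outside & ~np.isfinite(out)
    if edge.any():
        fill = ndimage.map_coordinates(
            src_f, [row_c[edge], col_c[edge]], order=order,
            mode="nearest")
        out[edge] = fill
    out = np.where(outside | ~np.isfinite(out), target.nodata, out)
    if kind == CATEGORICAL:
        ok = out != target.nodata
        out[ok] = np.round(out[ok])
    return target.copy_with(out)


def resample_stack(sources: dict[str, RasterGrid], target: RasterGrid,
                   kinds: dict[str, str] | None = None) -> EnvStack:
    """Resample several source rasters onto a shared target grid.

    Nodata masks of the resampled layers are unioned, so every layer in
    the output stack is valid on exactly the same cells.
    """
    kinds = kinds or {}
    layers = {
        name: resample_to_grid(g, target, kinds.get(name, CONTINUOUS))
        for name, g in sources.items()
    }
    union = np.zeros(target.shape, bool)
    for g in layers.values():
        union |= g.mask
    for name, g in layers.items():
        data = np.where(union, target.nodata, g.data)
        layers[name] = target.copy_with(data)
    meta = {n: {"kind": kinds.get(n, CONTINUOUS)} for n in layers}
    return EnvStack(layers=layers, meta=meta)


@dataclass
class SelectionReport:
    """Outcome of the iterative collinearity pruning.

    ``kept`` lists survivors in their original order (categorical layers
    are exempt from screening and always kept); ``removed`` records each
    eliminated variable with its mean |r| at removal time; ``corr`` is the
    final Pearson matrix of the kept continuous variables; ``vif`` their
    variance inflation factors.
    """

    kept: list[str]
    removed: list[tuple[str, float]]
    corr: pd.DataFrame
    vif: dict[str, float] = field(default_factory=dict)
    threshold: float = 0.7

    def write(self, stem: str | Path) -> None:
        stem = Path(stem)
        self.corr.to_csv(stem.with_suffix(".corr.csv"))
        pd.DataFrame({
            "variable": [n for n, _ in self.removed],
            "mean_abs_r_at_removal": [r for _, r in self.removed],
        }).to_csv(stem.with_suffix(".removed.csv"), index=False)
        import json

        stem.with_suffix(".json").write_text(json.dumps({
            "kept": self.kept,
            "removed": self.removed,
            "vif": self.vif,
            "threshold": self.threshold,
        }, indent=1))


def sample_cells(stack: EnvStack, n: int = 10_000, seed: int = 0):
    """Fixed random sample of non-nodata cells (as x, y coordinates)."""
    valid = ~stack.mask
    rows, cols = np.nonzero(valid)
    rng = np.random.default_rng(seed)
    if n < rows.size:
        idx = rng.choice(rows.size, size=n, replace=False)
        rows, cols = rows[idx], cols[idx]
    return stack.grid.centroid(rows, cols)


def correlation_matrix(stack: EnvStack, x, y,
                       names: Sequence[str] | None = None) -> pd.DataFrame:
    """Pearson correlation matrix of continuous layers at sample points."""
    names = list(names) if names is not None else stack.continuous
    df = stack.extract(x, y, names).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 valid sample locations")
    return df.corr(method="pearson")


def iterative_prune(get_corr, variables: list[str], threshold: float = 0.7,
                    priority: Sequence[str] = ()):
    """Iterative removal loop shared by matrix- and data-driven selection.

    ``get_corr(names)`` returns the Pearson matrix of the named variables
    (recomputed each round). While any off-diagonal |r| exceeds the
    threshold, removes — among variables in a violating pair, never a
    priority variable — the one with the highest mean absolute
    correlation to all remaining variables (ties: lexicographically later
    name). Returns ``(remaining, removed, final_corr)``.
    """
    priority = list(priority)
    remaining = list(variables)
    removed: list[tuple[str, float]] = []
    corr = get_corr(remaining)
    while True:
        absr = corr.loc[remaining, remaining].abs()
        np.fill_diagonal(absr.values, 0.0)
        violating = absr > threshold
        if not violating.to_numpy().any():
            break
        for a in priority:
            for b in priority:
                if a < b and a in remaining and b in remaining \
                        and violating.loc[a, b]:
                    raise IrreducibleConflictError(
                        f"priority variables {a!r} and {b!r} have "
                        f"|r| = {absr.loc[a, b]:.3f} > {threshold}")
        candidates = [v for v in remaining
                      if violating.loc[v].any() and v not in priority]
        if not candidates:
            raise IrreducibleConflictError(
                "all variables in violating pairs are priority-protected")
        mean_abs = {
            v: absr.loc[v, [w for w in remaining if w != v]].mean()
            for v in candidates
        }
        top = max(mean_abs.values())
        worst = max(v for v in candidates if np.isclose(mean_abs[v], top))
        removed.append((worst, float(mean_abs[worst])))
        remaining.remove(worst)
        corr = get_corr(remaining)
    return remaining, removed, corr.loc[remaining, remaining]


def select_from_matrix(corr: pd.DataFrame, threshold: float = 0.7,
                       priority: Sequence[str] = ()) -> SelectionReport:
    """Run the iterative pruning on a given correlation matrix.

    Recomputation each round takes the submatrix of the remaining
    variables. Useful for worked examples and audits of published
    matrices; VIFs are not computed (no underlying data).
    """
    remaining, removed, final = iterative_prune(
        lambda names: corr.loc[names, names], list(corr.columns),
        threshold=threshold, priority=priority)
    return SelectionReport(kept=remaining, removed=removed, corr=final,
                           vif={}, threshold=threshold)


def correlation_select(
    stack: EnvStack,
    x=None, y=None,
    threshold: float = 0.7,
    priority: Sequence[str] = (),
    sample_n: int = 10_000,
    seed: int = 0,
) -> SelectionReport:
    """Iteratively prune highly correlated continuous predictors.

    Each round recomputes the Pearson matrix over the remaining variables,
    finds pairs with |r| > ``threshold``, and removes — among variables in
    at least one violating pair, never a priority variable — the one with
    the highest mean absolute correlation to all remaining variables (ties
    broken by removing the lexicographically later name). Stops when no
    pair violates. Categorical layers are exempt (Pearson is undefined for
    nominal codes) and always kept.

    Raises :class:`IrreducibleConflictError` if two priority variables
    violate the threshold with each other.
    """
    priority = list(priority)
    unknown = [p for p in priority if p not in stack.names]
    if unknown:
        raise KeyError(f"priority variables not in stack: {unknown}")
    if x is None or y is None:
        x, y = sample_cells(stack, n=sample_n, seed=seed)
    remaining, removed, final_corr = iterative_prune(
        lambda names: correlation_matrix(stack, x, y, names),
        list(stack.continuous), threshold=threshold, priority=priority)
    kept = [n for n in stack.names
            if n in remaining or stack.kind(n) == CATEGORICAL]
    offdiag = final_corr.abs().to_numpy() - np.eye(len(remaining))
    assert offdiag.max(initial=0.0) < threshold, \
        "post-selection correlation audit failed"
    vifs = vif(stack, remaining, x, y)
    if any(v >= 5 for v in vifs.values()):
        log.warning("VIF >= 5 among kept variables: %s",
                    {k: v for k, v in vifs.items() if v >= 5})
    return SelectionReport(kept=kept, removed=removed, corr=final_corr,
                           vif=vifs, threshold=threshold)


def vif(stack: EnvStack, kept: Sequence[str], x=None, y=None,
        sample_n: int = 10_000, seed: int = 0) -> dict[str, float]:
    """Variance inflation factors of the kept continuous predictors.

    ``VIF_j = 1 / (1 - R^2_j)`` from an OLS regression of predictor *j* on
    the other kept continuous predictors (with intercept). Perfect
    collinearity yields ``inf`` (with a warning). A single predictor has
    VIF 1 by convention.
    """
    kept = [k for k in kept if stack.kind(k) == CONTINUOUS]
    if x is None or y is None:
        x, y = sample_cells(stack, n=sample_n, seed=seed)
    df = stack.extract(x, y, kept).dropna()
    if len(df) < len(kept) + 2:
        raise ValueError("need at least kept-count + 2 sample locations")
    out: dict[str, float] = {}
    vals = df.to_numpy(float)
    n = vals.shape[0]
    for j, name in enumerate(kept):
        others = np.delete(vals, j, axis=1)
        yj = vals[:, j]
        if others.shape[1] == 0:
            out[name] = 1.0
            continue
        X = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(X, yj, rcond=None)
        resid = yj - X @ beta
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
        if r2 >= 1.0 - 1e-12:
            log.warning("predictor %r is perfectly collinear; VIF = inf",
                        name)
            out[name] = float("inf")
        else:
            out[name] = float(1.0 / (1.0 - r2))
    return out
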