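"""Spatial block cross-validation and model-selection metrics.

The study area is split into spatially contiguous blocks (by default the
four quadrants around the presence median longitude/latitude); each fold
trains on all blocks but one and validates on the held-out block, limiting
the optimism that spatial autocorrelation induces in random CV.

Metrics: rank-based AUC; AUC_diff = |train - validation| AUC as an
overfitting gauge; sample-size-corrected AIC computed from the presence
likelihood under the standardized raw output with k = non-zero
coefficients; and the Continuous Boyce Index (CBI), the Spearman
correlation between moving-window presence-to-expected frequency ratios
and suitability — the natural calibration metric for presence-only data.

``tune_and_select`` runs the full grid of feature-class configurations and
regularization multipliers (5 x 10 = 50 candidates by default), ranks by
AICc, and picks the candidate with the lowest AUC_diff (ties: highest CBI)
within a caller-chosen feature family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

log = logging.getLogger(__name__)

DEFAULT_CLASS_GRID = ("L", "LQ", "LQH", "LQHP", "LQHPT")
DEFAULT_MULT_GRID = tuple(np.arange(0.5, 5.01, 0.5))


class UndefinedCBIError(ValueError):
    """Too few populated windows (or constant ratios) to define the CBI."""


@dataclass
class FoldAssignment:
    """Block ids (1..k) for every presence and background point."""

    presence_block: np.ndarray
    background_block: np.ndarray
    k: int

    def folds(self):
        """Yield (fold_block, train_pres, val_pres, train_bg, val_bg) masks."""
        for b in range(1, self.k + 1):
            yield (b,
                   self.presence_block != b, self.presence_block == b,
                   self.background_block != b, self.background_block == b)


def assign_blocks(
    presence_xy: tuple[np.ndarray, np.ndarray],
    background_xy: tuple[np.ndarray, np.ndarray],
    k: int = 4,
    method: str = "quadrant",
    seed: int = 0,
) -> FoldAssignment:
    """Partition presences and background into k spatial blocks.

    ``quadrant`` (k = 4) splits at the median presence longitude and
    latitude; k = 2 splits at the median longitude only. Other k (or
    ``method="kmeans"``) cluster presence coordinates with k-means and
    assign background points to the nearest centroid. Errors if any block
    holds no presences.
    """
    px, py = (np.asarray(a, float) for a in presence_xy)
    bx, by = (np.asarray(a, float) for a in background_xy)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(px) < k:
        raise ValueError("need at least k presences")

    if method == "quadrant" and k in (2, 4):
        mx = np.median(px)
        if k == 2:
            pb = np.where(px <= mx, 1, 2)
            bb = np.where(bx <= mx, 1, 2)
        else:
            my = np.median(py)
            pb = 1 + (px > mx).astype(int) + 2 * (py > my).astype(int)
            bb = 1 + (bx > mx).astype(int) + 2 * (by > my).astype(int)
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        pb = km.fit_predict(np.column_stack([px, py])) + 1
        bb = km.predict(np.column_stack([bx, by])) + 1
    counts = np.bincount(pb, minlength=k + 1)[1:]
    if (counts == 0).any():
        raise ValueError(
            f"a spatial block holds no presences (counts {counts.tolist()}); "
            "try a smaller k")
    return FoldAssignment(presence_block=pb, background_block=bb, k=k)


def auc_score(pred_presence, pred_background) -> float:
    """Rank-based AUC: P(random presence outranks random background).

    Ties count one half. Equivalent to the Mann-Whitney U statistic
    normalized by the number of pairs.
    """
    p = np.asarray(pred_presence, float)
    b = np.asarray(pred_background, float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both prediction sets must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[:p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


def aicc_score(results, presence_values: pd.DataFrame | None = None) -> float:
    """Sample-size-corrected AIC of a fitted model.

    ``k`` counts non-zero coefficients; the log-likelihood is the sum over
    presences of the log raw output (already standardized to sum to 1 over
    the model's background). Undefined when n <= k + 1; returns +inf with
    a warning so the candidate cannot win model selection.
    """
    if presence_values is None:
        presence_values = results.model.presence
    raw = results.predict(presence_values, mode="raw")
    n = len(presence_values)
    k = results.n_params
    if n <= k + 1:
        log.warning("AICc undefined: n=%d <= k+1=%d", n, k + 1)
        return float("inf")
    lnL = float(np.sum(np.log(np.maximum(raw, 1e-300))))
    return float(2 * k - 2 * lnL + 2 * k * (k + 1) / (n - k - 1))


def boyce_index(
    pred_presence,
    pred_reference,
    n_windows: int = 101,
    window_frac: float = 0.1,
) -> float:
    """Continuous Boyce Index over moving suitability windows.

    Windows of width ``window_frac * (max - min)`` are centered at
    ``n_windows`` evenly spaced midpoints spanning the reference
    prediction range. For each window, F = (share of presence predictions
    inside) / (share of reference predictions inside); the CBI is the
    Spearman rank correlation between F and the window midpoints.
    Perfectly calibrated rankings give values near 1, inverted rankings
    near -1, uninformative ones near 0.
    """
    p = np.asarray(pred_presence, float)
    r = np.asarray(pred_reference, float)
    if r.size == 0 or p.size == 0:
        raise ValueError("presence and reference predictions required")
    lo, hi = float(r.min()), float(r.max())
    if hi <= lo:
        raise UndefinedCBIError("reference predictions are constant")
    width = window_frac * (hi - lo)
    mids = np.linspace(lo, hi, n_windows)
    F, kept_mids = [], []
    for mid in mids:
        a, b = mid - width / 2, mid + width / 2
        e = np.mean((r >= a) & (r <= b))
        if e <= 0:
            continue
        pe = np.mean((p >= a) & (p <= b))
        F.append(pe / e)
        kept_mids.append(mid)
    if len(F) < 3:
        raise UndefinedCBIError(
            f"only {len(F)} windows with expected frequency > 0")
    F = np.asarray(F)
    if np.allclose(F, F[0]):
        raise UndefinedCBIError("P/E ratio is constant across windows")
    rho, _ = spearmanr(F, kept_mids)
    return float(rho)


def tune_and_select(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    presence_xy: tuple[np.ndarray, np.ndarray],
    background_xy: tuple[np.ndarray, np.ndarray],
    classes_grid: Sequence[str] = DEFAULT_CLASS_GRID,
    mult_grid: Sequence[float] = DEFAULT_MULT_GRID,
    k: int = 4,
    categorical: Sequence[str] = (),
    n_knots: int = 50,
    family: str | None = None,
    cbi_windows: int = 101,
) -> tuple[pd.DataFrame, dict]:
    """Grid-search feature classes x regularization multipliers.

    For every combination the model is fitted on the full data (for AICc)
    and cross-validated over spatial blocks (for train/validation AUC,
    AUC_diff and CBI, reported as mean +/- sd over folds). The returned
    table is ranked by AICc (ties: fewer parameters, then lower
    multiplier). The *selected* candidate minimizes mean AUC_diff (ties:
    maximal mean CBI) within ``family`` if given, else over the whole
    grid — mirroring a final choice made inside one ecologically
    interpretable feature family.

    Candidates whose fit fails in any fold are excluded from ranking and
    logged. Returns ``(table, selected_row_dict)``.
    """
    from .model import MaxEnt

    folds = assign_blocks(presence_xy, background_xy, k=k)
    rows = []
    for classes in classes_grid:
        for mult in mult_grid:
            entry = {"classes": classes, "reg_mult": float(mult)}
            try:
                full = MaxEnt(presence, background, classes=classes,
                              reg_mult=mult, categorical=categorical,
                              n_knots=n_knots).fit(raise_on_failure=False)
                entry["n_params"] = full.n_params
                entry["aicc"] = aicc_score(full)
                tr_auc, va_auc, cbis = [], [], []
                for _, tp, vp, tb, vb in folds.folds():
                    fold_fit = MaxEnt(
                        presence[tp], background[tb], classes=classes,
                        reg_mult=mult, categorical=categorical,
                        n_knots=n_knots).fit(raise_on_failure=False)
                    pred_tp = fold_fit.predict(presence[tp], mode="raw")
                    pred_tb = fold_fit.predict(background[tb], mode="raw")
                    pred_vp = fold_fit.predict(presence[vp], mode="raw")
                    pred_vb = fold_fit.predict(background[vb], mode="raw")
                    tr_auc.append(auc_score(pred_tp, pred_tb))
                    va_auc.append(auc_score(pred_vp, pred_vb))
                    cl_vp = fold_fit.predict(presence[vp], mode="cloglog")
                    cl_vb = fold_fit.predict(background[vb], mode="cloglog")
                    try:
                        cbis.append(boyce_index(cl_vp, cl_vb,
                                                n_windows=cbi_windows))
                    except UndefinedCBIError:
                        cbis.append(np.nan)
                tr, va = np.asarray(tr_auc), np.asarray(va_auc)
                diff = np.abs(tr - va)
                entry.update({
                    "auc_train": tr.mean(), "auc_val": va.mean(),
                    "auc_diff": diff.mean(), "auc_diff_sd": diff.std(ddof=1),
                    "cbi": np.nanmean(cbis), "cbi_sd": np.nanstd(cbis, ddof=1),
                    "failed": False,
                })
            except Exception as exc:  # noqa: BLE001 - candidate isolation
                log.warning("candidate %s x %.1f failed: %s",
                            classes, mult, exc)
                entry.update({"failed": True, "aicc": np.inf,
                              "n_params": -1})
            rows.append(entry)
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]].copy()
    ok = ok.sort_values(["aicc", "n_params", "reg_mult"],
                        kind="mergesort", ignore_index=True)
    ok["aicc_rank"] = np.arange(1, len(ok) + 1)
    failed = table[table["failed"]]
    table = pd.concat([ok, failed], ignore_index=True) if len(failed) else ok

    pool = ok if family is None else ok[ok["classes"] == family]
    if len(pool) == 0:
        raise ValueError(f"no successful candidates in family {family!r}")
    pool = pool.sort_values(["auc_diff", "cbi", "aicc"],
                            ascending=[True, False, True], kind="mergesort")
    selected = pool.iloc[0].to_dict()
    return table, selected
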