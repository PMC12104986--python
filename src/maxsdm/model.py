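"""The presence-background maximum-entropy model.

The model fits a Gibbs (log-linear) distribution over landscape cells,

    raw(x) = exp(sum_j beta_j f_j(x)) / Z,

with Z normalizing over a background sample of the study area, by
maximizing the penalized log-likelihood of the presence records

    (1/n) sum_i eta(x_i) - log Z - sum_j lambda_j |beta_j|,

where ``lambda_j = reg_mult * base(class_j, n) * sd_j / sqrt(n)`` follows
the published per-feature-class defaults. The optimization is convex; it
is solved exactly by splitting each coefficient into positive and negative
parts and running bound-constrained L-BFGS-B.

Two outputs are exposed: the *raw* density (sums to 1 over the background)
and the *cloglog* transform ``1 - exp(-exp(H) * raw)``, where H is the
entropy of the fitted raw distribution; a cell expected to hold one
individual then scores 1 - 1/e ~ 0.632.

Usage follows the statsmodels convention: build a :class:`MaxEnt` model
from data, call :meth:`MaxEnt.fit`, and work with the returned
:class:`MaxEntResults` (prediction, response curves, variable importance,
``summary()``).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .features import FeatureSet, regularization_base
from .raster import EnvStack, RasterGrid

log = logging.getLogger(__name__)

ZERO_TOL = 1e-8  # coefficients below this magnitude count as zero


class ConvergenceError(RuntimeError):
    """The optimizer failed to reach the requested tolerance."""


class DegenerateModelError(ValueError):
    """No usable features remain after preprocessing."""


def sample_background(stack: EnvStack, n: int, seed: int = 0) -> pd.DataFrame:
    """Uniform background sample of cell centroids, without replacement.

    Returns a DataFrame with ``x``/``y`` columns plus one column per layer.
    ``n`` may not exceed the number of valid (non-nodata) cells; with
    ``n`` equal to that count every cell appears exactly once.
    """
    valid = ~stack.mask
    rows, cols = np.nonzero(valid)
    if n > rows.size:
        raise ValueError(
            f"requested {n} background points but only {rows.size} valid cells")
    rng = np.random.default_rng(seed)
    idx = rng.choice(rows.size, size=n, replace=False) if n < rows.size \
        else np.arange(rows.size)
    rows, cols = rows[idx], cols[idx]
    x, y = stack.grid.centroid(rows, cols)
    df = pd.DataFrame({"x": x, "y": y})
    for name in stack.names:
        df[name] = stack[name].values[rows, cols]
    return df


class MaxEnt:
    """Maximum-entropy presence-background model (unfitted).

    Parameters
    ----------
    presence : DataFrame of predictor values at presence records.
    background : DataFrame of predictor values at background points.
    classes : feature classes as a string over {L, Q, P, H, T}.
    reg_mult : global regularization multiplier (> 0); larger values give
        sparser, smoother models.
    categorical : names of categorical predictors (expanded to indicators).
    n_knots : hinge/threshold knots per variable per direction.
    clamp : pin out-of-range values to the training range at prediction
        time (recommended when transferring to future climates).
    """

    def __init__(
        self,
        presence: pd.DataFrame,
        background: pd.DataFrame,
        classes: str = "LQ",
        reg_mult: float = 1.0,
        categorical: Sequence[str] = (),
        n_knots: int = 50,
        clamp: bool = False,
    ) -> None:
        if reg_mult <= 0:
            raise ValueError("reg_mult must be > 0")
        drop = [c for c in ("x", "y") if c in presence.columns]
        variables = [c for c in background.columns if c not in ("x", "y")]
        self.presence = presence.drop(columns=drop, errors="ignore")[
            [c for c in variables if c in presence.columns]].dropna()
        self.background = background[variables].dropna()
        if len(self.presence) < 2:
            raise ValueError("need at least 2 presence records")
        if len(self.background) == 0:
            raise ValueError("background must be non-empty")
        self.classes = classes.upper()
        self.reg_mult = float(reg_mult)
        self.categorical = [c for c in categorical if c in variables]
        self.n_knots = int(n_knots)
        self.clamp = bool(clamp)

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_stack(
        cls,
        stack: EnvStack,
        presences,
        n_background: int = 20_000,
        seed: int = 0,
        **kwargs,
    ) -> "MaxEnt":
        """Build the model from an environment stack and occurrence set.

        Presence predictor values are extracted at the occurrence
        coordinates; the background is a uniform sample of
        ``n_background`` cell centroids (presences not excluded).
        """
        x, y = presences.xy
        pres = stack.extract(x, y).dropna()
        bg = sample_background(stack, n_background, seed=seed)
        kwargs.setdefault("categorical", stack.categorical)
        return cls(presence=pres, background=bg, **kwargs)

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        tol: float = 1e-9,
        maxiter: int = 10_000,
        raise_on_failure: bool = True,
    ) -> "MaxEntResults":
        """Fit the penalized model; returns :class:`MaxEntResults`."""
        features = FeatureSet.build(
            pd.concat([self.presence, self.background], ignore_index=True),
            classes=self.classes,
            categorical=self.categorical,
            n_knots=self.n_knots,
        )
        if len(features) == 0:
            raise DegenerateModelError("no usable features")
        F_p = features.transform(self.presence)
        F_b = features.transform(self.background)
        n = len(self.presence)

        # Per-feature penalty: reg_mult * class base * sd over presences
        # / sqrt(n). The sd is floored so near-constant features are still
        # penalized rather than free.
        sd = F_p.std(axis=0, ddof=0)
        sd = np.maximum(sd, 1e-4)
        base = np.array([regularization_base(d.kind, n) for d in features.defs])
        lam = self.reg_mult * base * sd / np.sqrt(n)

        fbar = F_p.mean(axis=0)
        m = len(features)
        lam2 = np.concatenate([lam, lam])

        def objective(theta):
            beta = theta[:m] - theta[m:]
            eta_b = F_b @ beta
            lz = logsumexp(eta_b)
            p_b = np.exp(eta_b - lz)
            f = -fbar @ beta + lz + lam2 @ theta
            g_beta = -fbar + F_b.T @ p_b
            grad = np.concatenate([g_beta + lam, -g_beta + lam])
            return f, grad

        theta0 = np.zeros(2 * m)
        res = minimize(
            objective, theta0, jac=True, method="L-BFGS-B",
            bounds=[(0, None)] * (2 * m),
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-9,
                     "maxfun": 10 * maxiter},
        )
        if not res.success and raise_on_failure and res.status != 1:
            raise ConvergenceError(
                f"L-BFGS-B did not converge: {res.message} "
                f"(nit={res.nit}, |grad|~{np.max(np.abs(res.jac)):.2e})")
        theta = res.x
        beta = theta[:m] - theta[m:]
        beta[np.abs(beta) < ZERO_TOL] = 0.0

        eta_b = F_b @ beta
        logZ = logsumexp(eta_b)
        raw_b = np.exp(eta_b - logZ)
        entropy = float(-(raw_b * np.log(np.maximum(raw_b, 1e-300))).sum())
        return MaxEntResults(
            model=self,
            features=features,
            beta=beta,
            lam=lam,
            logZ=float(logZ),
            entropy=entropy,
            raw_background=raw_b,
            objective=float(res.fun),
            converged=bool(res.success),
            n_iter=int(res.nit),
        )


class MaxEntResults:
    """A fitted maximum-entropy model.

    Carries coefficients, the background normalizer ``Z`` (stored as
    ``logZ``), the entropy ``H`` of the fitted raw distribution, the
    penalty vector, and the training feature expansion. Prediction,
    response curves, variable importance and serialization live here.
    """

    def __init__(
        self,
        model: MaxEnt | None,
        features: FeatureSet,
        beta: np.ndarray,
        lam: np.ndarray,
        logZ: float,
        entropy: float,
        raw_background: np.ndarray | None = None,
        objective: float = float("nan"),
        converged: bool = True,
        n_iter: int = 0,
        clamp: bool | None = None,
    ) -> None:
        self.model = model
        self.features = features
        self.beta = np.asarray(beta, float)
        self.lam = np.asarray(lam, float)
        self.logZ = float(logZ)
        self.entropy = float(entropy)
        self.raw_background = raw_background
        self.objective = objective
        self.converged = converged
        self.n_iter = n_iter
        self._clamp = clamp if clamp is not None else (
            model.clamp if model is not None else False)

    # -- basic accessors ----------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.features.labels, name="beta")

    @property
    def Z(self) -> float:
        return float(np.exp(self.logZ))

    @property
    def n_params(self) -> int:
        """Number of non-zero coefficients (the AICc k)."""
        return int(np.sum(np.abs(self.beta) > ZERO_TOL))

    @property
    def variables(self) -> list[str]:
        return self.features.variables

    # -- prediction ---------------------------------------------------------
    def linear_predictor(self, values: pd.DataFrame,
                         clamp: bool | None = None) -> np.ndarray:
        clamp = self._clamp if clamp is None else clamp
        F = self.features.transform(values, clamp=clamp)
        return F @ self.beta

    def predict(
        self,
        values: pd.DataFrame,
        mode: Literal["raw", "cloglog"] = "cloglog",
        clamp: bool | None = None,
    ) -> np.ndarray:
        """Predict at a table of predictor values.

        ``raw`` is the Gibbs density normalized over the training
        background; ``cloglog`` maps it to (0, 1) via
        ``1 - exp(-exp(H) * raw)``.
        """
        eta = self.linear_predictor(values, clamp=clamp)
        raw = np.exp(eta - self.logZ)
        if mode == "raw":
            return raw
        if mode == "cloglog":
            return 1.0 - np.exp(-np.exp(self.entropy) * raw)
        raise ValueError(f"unknown mode {mode!r}")

    def predict_stack(
        self,
        stack: EnvStack,
        mode: Literal["raw", "cloglog"] = "cloglog",
        clamp: bool | None = None,
    ) -> RasterGrid:
        """Predict over every valid cell of a stack; returns a raster."""
        missing = [v for v in self.variables if v not in stack]
        if missing:
            raise KeyError(f"stack is missing model variables {missing}")
        table, rows, cols = stack.table(self.variables)
        pred = self.predict(table, mode=mode, clamp=clamp)
        out = np.full(stack.grid.shape, stack.grid.nodata)
        out[rows, cols] = pred
        return stack.grid.copy_with(out)

    # -- interpretation -----------------------------------------------------
    def response_curve(
        self,
        variable: str,
        n_steps: int = 100,
        others_at: Literal["mean", "median"] = "mean",
    ) -> pd.DataFrame:
        """Marginal response: sweep one variable, hold the others fixed.

        Continuous covariates are fixed at their background mean (or
        median); categorical ones at their modal class. Returns a
        DataFrame with columns ``value`` (raw units) and ``cloglog``.
        """
        if variable not in self.variables:
            raise KeyError(f"variable {variable!r} not in model")
        if self.model is None:
            raise ValueError("response curves need the training background")
        bg = self.model.background
        fixed: dict[str, float] = {}
        for v in self.variables:
            col = bg[v]
            if v in self.features.categorical:
                fixed[v] = float(col.mode().iloc[0])
            else:
                fixed[v] = float(col.mean() if others_at == "mean"
                                 else col.median())
        if variable in self.features.categorical:
            sweep = np.sort(bg[variable].dropna().unique())
        else:
            lo, hi = self.features.scales[variable]
            sweep = np.linspace(lo, hi, n_steps)
        table = pd.DataFrame({v: np.full(len(sweep), fixed[v])
                              for v in self.variables})
        table[variable] = sweep
        return pd.DataFrame({
            "value": sweep,
            "cloglog": self.predict(table, mode="cloglog"),
        })

    def variable_importance(
        self,
        n_permutations: int = 5,
        seed: int = 0,
    ) -> pd.DataFrame:
        """Percent contribution and permutation importance per variable.

        Permutation importance: shuffle one variable's raw values jointly
        across presences and background (all of its features are rebuilt),
        measure the drop in training AUC, average over permutations, and
        normalize the drops to sum to 100. Percent contribution is a
        coefficient-magnitude proxy: ``|beta_j| * sd(f_j)`` over the
        background, summed per variable and normalized to 100.
        """
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.model is None:
            raise ValueError("variable importance needs the training data")
        from .evaluate import auc_score

        pres, bg = self.model.presence, self.model.background
        n_p = len(pres)
        combined = pd.concat([pres[self.variables], bg[self.variables]],
                             ignore_index=True)
        base_pred = self.predict(combined, mode="raw")
        base_auc = auc_score(base_pred[:n_p], base_pred[n_p:])

        F_b = self.features.transform(bg[self.variables])
        contrib = {v: 0.0 for v in self.variables}
        for j, d in enumerate(self.features.defs):
            w = abs(self.beta[j]) * F_b[:, j].std()
            if d.kind == "product":
                contrib[d.var] += w / 2
                contrib[d.var2] += w / 2
            else:
                contrib[d.var] += w
        total = sum(contrib.values())
        pct_contrib = {v: (100.0 * c / total if total > 0 else 0.0)
                       for v, c in contrib.items()}

        rng = np.random.default_rng(seed)
        drops = {v: 0.0 for v in self.variables}
        for v in self.variables:
            for _ in range(n_permutations):
                shuffled = combined.copy()
                shuffled[v] = rng.permutation(shuffled[v].to_numpy())
                pred = self.predict(shuffled, mode="raw")
                drops[v] += base_auc - auc_score(pred[:n_p], pred[n_p:])
            drops[v] = max(drops[v] / n_permutations, 0.0)
        total_drop = sum(drops.values())
        perm = {v: (100.0 * d / total_drop if total_drop > 0 else 0.0)
                for v, d in drops.items()}
        out = pd.DataFrame({
            "variable": self.variables,
            "percent_contribution": [pct_contrib[v] for v in self.variables],
            "permutation_importance": [perm[v] for v in self.variables],
        })
        return out.sort_values("percent_contribution", ascending=False,
                               ignore_index=True)

    # -- reporting ----------------------------------------------------------
    def summary(self, top: int = 15) -> str:
        """Human-readable fit summary in the statsmodels spirit."""
        lines = [
            "Maximum-entropy presence-background model",
            "=" * 57,
            f"presences: {len(self.model.presence) if self.model else 'n/a':>8}"
            f"    background: "
            f"{len(self.model.background) if self.model else 'n/a'}",
            f"feature classes: {self.model.classes if self.model else '?':<6}"
            f" reg. multiplier: "
            f"{self.model.reg_mult if self.model else float('nan'):g}",
            f"features: {len(self.features):>9}    non-zero coef: "
            f"{self.n_params}",
            f"log Z: {self.logZ:>12.5f}    entropy H: {self.entropy:.5f}",
            f"converged: {self.converged}    iterations: {self.n_iter}",
            "-" * 57,
            f"{'feature':<34}{'beta':>12}{'lambda':>11}",
        ]
        order = np.argsort(-np.abs(self.beta))
        shown = 0
        for j in order:
            if shown >= top or self.beta[j] == 0.0:
                break
            lines.append(f"{self.features.labels[j]:<34}"
                         f"{self.beta[j]:>12.5f}{self.lam[j]:>11.5f}")
            shown += 1
        if self.n_params > shown:
            lines.append(f"... {self.n_params - shown} more non-zero "
                         "coefficients")
        lines.append("=" * 57)
        return "\n".join(lines)

    def plot_response(self, variable: str, ax=None, **kwargs):
        """Plot a response curve on a matplotlib axis."""
        import matplotlib.pyplot as plt

        curve = self.response_curve(variable, **kwargs)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve["value"], curve["cloglog"])
        ax.set_xlabel(variable)
        ax.set_ylabel("suitability (cloglog)")
        return ax

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "features": self.features.to_dict(),
            "beta": self.beta.tolist(),
            "lambda": self.lam.tolist(),
            "logZ": self.logZ,
            "entropy": self.entropy,
            "clamp": self._clamp,
            "config": {
                "classes": self.model.classes if self.model else None,
                "reg_mult": self.model.reg_mult if self.model else None,
                "n_knots": self.model.n_knots if self.model else None,
            },
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MaxEntResults":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        d = json.loads(text)
        return cls(
            model=None,
            features=FeatureSet.from_dict(d["features"]),
            beta=np.asarray(d["beta"]),
            lam=np.asarray(d["lambda"]),
            logZ=d["logZ"],
            entropy=d["entropy"],
            clamp=d.get("clamp", False),
        )
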