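"""Feature expansion for the maximum-entropy model.

Continuous predictors are rescaled to [0, 1] by their training (min, max)
and expanded into the classic feature classes:

* ``L`` linear — the scaled value itself;
* ``Q`` quadratic — its square;
* ``P`` product — pairwise products of distinct continuous variables;
* ``H`` hinge — forward ramps ``max(0, (v-t)/(1-t))`` and reverse ramps
  ``max(0, (t-v)/t)`` at empirical quantile knots;
* ``T`` threshold — step functions ``1[v > t]`` at quantile knots.

Categorical variables always expand to one indicator per observed class,
whatever the requested classes. Out-of-range values at prediction time can
be clamped to the training range (used when transferring to new climates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FEATURE_CLASSES = ("L", "Q", "P", "H", "T")


@dataclass(frozen=True)
class FeatureDef:
    """One model feature: its class, variable(s) and parameters."""

    kind: str                     # linear|quadratic|product|forward-hinge|
    #                               reverse-hinge|threshold|indicator
    var: str
    var2: str | None = None      # product features only
    knot: float | None = None    # hinge/threshold, on the [0,1] scale
    category: float | None = None  # indicator features only

    def __post_init__(self) -> None:
        if self.kind == "product" and self.var2 is None:
            raise ValueError("product feature needs two variables")
        if self.kind in {"forward-hinge", "reverse-hinge", "threshold"}:
            if self.knot is None or not (0.0 < self.knot < 1.0):
                raise ValueError("knot must lie strictly inside (0, 1)")
        if self.kind == "indicator" and self.category is None:
            raise ValueError("indicator feature needs a category code")

    @property
    def label(self) -> str:
        if self.kind == "product":
            return f"P({self.var}*{self.var2})"
        if self.kind in {"forward-hinge", "reverse-hinge", "threshold"}:
            tag = {"forward-hinge": "Hf", "reverse-hinge": "Hr",
                   "threshold": "T"}[self.kind]
            return f"{tag}({self.var}@{self.knot:.4g})"
        if self.kind == "indicator":
            return f"I({self.var}={self.category:g})"
        return f"{'L' if self.kind == 'linear' else 'Q'}({self.var})"


class FeatureSet:
    """A fitted feature expansion: scaling ranges plus feature definitions.

    Built once from training data (presences + background) and then used
    to transform any table of predictor values into the model's design
    matrix.
    """

    def __init__(
        self,
        defs: list[FeatureDef],
        scales: dict[str, tuple[float, float]],
        categorical: Sequence[str] = (),
    ) -> None:
        self.defs = defs
        self.scales = dict(scales)
        self.categorical = list(categorical)

    # -- construction -----------------------------------------------------
    @classmethod
    def build(
        cls,
        values: pd.DataFrame,
        classes: str = "LQ",
        categorical: Sequence[str] = (),
        n_knots: int = 50,
    ) -> "FeatureSet":
        """Derive feature definitions from training predictor values.

        ``classes`` is a string over {L, Q, P, H, T}. Constant continuous
        variables are dropped with a warning. Hinge/threshold knots sit at
        empirical quantiles of the scaled training values, duplicates
        removed.
        """
        classes = classes.upper()
        bad = set(classes) - set(FEATURE_CLASSES)
        if not classes or bad:
            raise ValueError(f"classes must be a non-empty subset of "
                             f"{FEATURE_CLASSES}, got {classes!r}")
        categorical = [c for c in categorical if c in values.columns]
        continuous = [c for c in values.columns if c not in categorical]
        scales: dict[str, tuple[float, float]] = {}
        usable: list[str] = []
        for c in continuous:
            lo = float(np.nanmin(values[c]))
            hi = float(np.nanmax(values[c]))
            if not np.isfinite(lo) or not np.isfinite(hi) or lo == hi:
                log.warning("dropping constant/invalid variable %r", c)
                continue
            scales[c] = (lo, hi)
            usable.append(c)

        defs: list[FeatureDef] = []
        if "L" in classes:
            defs += [FeatureDef("linear", c) for c in usable]
        if "Q" in classes:
            defs += [FeatureDef("quadratic", c) for c in usable]
        if "P" in classes:
            for i, a in enumerate(usable):
                for b in usable[i + 1:]:
                    defs.append(FeatureDef("product", a, var2=b))
        if "H" in classes or "T" in classes:
            qs = np.linspace(0, 1, n_knots + 2)[1:-1]
            for c in usable:
                lo, hi = scales[c]
                v = (values[c].to_numpy(float) - lo) / (hi - lo)
                knots = np.unique(np.round(np.nanquantile(v, qs), 10))
                knots = knots[(knots > 0) & (knots < 1)]
                for t in knots:
                    if "H" in classes:
                        defs.append(FeatureDef("forward-hinge", c,
                                               knot=float(t)))
                        defs.append(FeatureDef("reverse-hinge", c,
                                               knot=float(t)))
                    if "T" in classes:
                        defs.append(FeatureDef("threshold", c,
                                               knot=float(t)))
        for c in categorical:
            codes = np.unique(values[c].to_numpy(float))
            codes = codes[np.isfinite(codes)]
            for code in codes:
                defs.append(FeatureDef("indicator", c, category=float(code)))
        if not defs:
            raise ValueError("no usable features could be built")
        return cls(defs=defs, scales=scales, categorical=categorical)

    # -- evaluation -------------------------------------------------------
    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for d in self.defs:
            for v in (d.var, d.var2):
                if v is not None and v not in seen:
                    seen.append(v)
        return seen

    @property
    def labels(self) -> list[str]:
        return [d.label for d in self.defs]

    def __len__(self) -> int:
        return len(self.defs)

    def scaled(self, values: pd.DataFrame, clamp: bool = False
               ) -> dict[str, np.ndarray]:
        """Rescale continuous columns to [0,1]; clamp pins outliers."""
        out: dict[str, np.ndarray] = {}
        for c, (lo, hi) in self.scales.items():
            if c not in values.columns:
                raise KeyError(f"variable {c!r} missing from input values")
            v = (values[c].to_numpy(float) - lo) / (hi - lo)
            if clamp:
                v = np.clip(v, 0.0, 1.0)
            out[c] = v
        for c in self.categorical:
            if c not in values.columns:
                raise KeyError(f"variable {c!r} missing from input values")
            out[c] = values[c].to_numpy(float)
        return out

    def transform(self, values: pd.DataFrame, clamp: bool = False
                  ) -> np.ndarray:
        """Design matrix (n_points x n_features) for a table of values."""
        sv = self.scaled(values, clamp=clamp)
        cols = np.empty((len(values), len(self.defs)))
        for j, d in enumerate(self.defs):
            v = sv[d.var]
            if d.kind == "linear":
                cols[:, j] = v
            elif d.kind == "quadratic":
                cols[:, j] = v * v
            elif d.kind == "product":
                cols[:, j] = v * sv[d.var2]
            elif d.kind == "forward-hinge":
                t = d.knot
                cols[:, j] = np.maximum(0.0, (v - t) / (1.0 - t))
            elif d.kind == "reverse-hinge":
                t = d.knot
                cols[:, j] = np.maximum(0.0, (t - v) / t)
            elif d.kind == "threshold":
                cols[:, j] = (v > d.knot).astype(float)
            elif d.kind == "indicator":
                cols[:, j] = (v == d.category).astype(float)
            else:  # pragma: no cover
                raise ValueError(f"unknown feature kind {d.kind!r}")
        return cols

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "defs": [asdict(d) for d in self.defs],
            "scales": {k: list(v) for k, v in self.scales.items()},
            "categorical": self.categorical,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureSet":
        return cls(
            defs=[FeatureDef(**dd) for dd in d["defs"]],
            scales={k: (v[0], v[1]) for k, v in d["scales"].items()},
            categorical=list(d["categorical"]),
        )


# Default per-class regularization bases, linearly interpolated in the
# presence sample size (the published defaults of the reference MaxEnt
# implementation). Values are clamped at the table ends.
_BASE_TABLES: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "lqp": ((0, 10, 30, 100), (1.0, 1.0, 0.2, 0.05)),
    "categorical": ((0, 10, 17), (0.65, 0.5, 0.25)),
    "threshold": ((0, 100), (2.0, 1.0)),
    "hinge": ((0, 1), (0.5, 0.5)),
}

_KIND_TO_TABLE = {
    "linear": "lqp", "quadratic": "lqp", "product": "lqp",
    "forward-hinge": "hinge", "reverse-hinge": "hinge",
    "threshold": "threshold", "indicator": "categorical",
}


def regularization_base(kind: str, n_presence: int) -> float:
    """Per-feature-class base penalty, interpolated by sample size."""
    xs, ys = _BASE_TABLES[_KIND_TO_TABLE[kind]]
    return float(np.interp(n_presence, xs, ys))
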