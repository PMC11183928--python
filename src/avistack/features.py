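"""Feature transforms for presence-background maximum-entropy models.

Environmental variables are expanded into the classic feature classes:

* ``L`` linear — the variable rescaled to [0, 1] over the background range;
* ``Q`` quadratic — the square of the rescaled variable;
* ``P`` product — pairwise products of rescaled continuous variables;
* ``H`` hinge — forward and reverse piecewise-linear ramps at knots placed at
  equally spaced background quantiles;
* ``T`` threshold — step indicators at the same knots;
* categorical variables always enter as one indicator per legend class.

Rescaling constants and knots are frozen from the background sample at build
time; prediction values outside the training range are clamped to it, so all
features map into [0, 1] everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Feature", "FeatureSet", "build_features", "FEATURE_CLASSES"]

FEATURE_CLASSES = ("L", "Q", "P", "H", "T")


@dataclass(frozen=True)
class Feature:
    """A single scalar feature: kind, source variable(s), and parameter."""

    name: str
    kind: str  # linear | quadratic | product | hinge_fwd | hinge_rev | threshold | categorical
    variables: tuple[str, ...]
    param: float = 0.0  # knot (hinge/threshold) or class code (categorical)


@dataclass
class FeatureSet:
    """Frozen feature definitions plus the scaling constants to evaluate them."""

    features: list[Feature]
    scaling: dict[str, tuple[float, float]]  # variable -> (min, max) on the background
    categorical_legend: dict[str, list[int]] = field(default_factory=dict)
    classes: tuple[str, ...] = ("L",)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def n_features(self) -> int:
        return len(self.features)

    def variables(self) -> list[str]:
        seen: list[str] = []
        for f in self.features:
            for v in f.variables:
                if v not in seen:
                    seen.append(v)
        return seen

    def penalty_class(self, f: Feature) -> str:
        return {
            "linear": "linear",
            "quadratic": "quadratic",
            "product": "product",
            "hinge_fwd": "hinge",
            "hinge_rev": "hinge",
            "threshold": "threshold",
            "categorical": "categorical",
        }[f.kind]

    def _rescale(self, var: str, x: np.ndarray) -> tuple[np.ndarray, int]:
        lo, hi = self.scaling[var]
        if hi <= lo:
            return np.zeros_like(x, dtype=float), 0
        clamped = np.clip(x, lo, hi)
        n_clamped = int(np.sum((x < lo) | (x > hi)))
        return (clamped - lo) / (hi - lo), n_clamped

    def design_matrix(self, values: dict[str, np.ndarray]) -> tuple[np.ndarray, int]:
        """Evaluate all features on per-variable value vectors.

        Returns the (n_cells, n_features) design and the count of values that
        had to be clamped to the training range.
        """
        scaled: dict[str, np.ndarray] = {}
        clamp_total = 0
        for var in self.scaling:
            x = np.asarray(values[var], dtype=float)
            if not np.all(np.isfinite(x)):
                bad = int(np.flatnonzero(~np.isfinite(x))[0])
                raise ValueError(f"non-finite value for variable {var!r} at cell {bad}")
            scaled[var], n_cl = self._rescale(var, x)
            clamp_total += n_cl
        if scaled:
            n = len(next(iter(scaled.values())))
        elif values:
            n = len(np.asarray(next(iter(values.values()))))
        else:
            n = 0
        cols = np.empty((n, len(self.features)), dtype=float)
        for j, f in enumerate(self.features):
            if f.kind == "linear":
                cols[:, j] = scaled[f.variables[0]]
            elif f.kind == "quadratic":
                cols[:, j] = scaled[f.variables[0]] ** 2
            elif f.kind == "product":
                cols[:, j] = scaled[f.variables[0]] * scaled[f.variables[1]]
            elif f.kind == "hinge_fwd":
                k = f.param
                cols[:, j] = np.clip((scaled[f.variables[0]] - k) / (1.0 - k), 0.0, 1.0) if k < 1 else 0.0
            elif f.kind == "hinge_rev":
                k = f.param
                cols[:, j] = np.clip((k - scaled[f.variables[0]]) / k, 0.0, 1.0) if k > 0 else 0.0
            elif f.kind == "threshold":
                cols[:, j] = (scaled[f.variables[0]] >= f.param).astype(float)
            elif f.kind == "categorical":
                var = f.variables[0]
                cols[:, j] = (np.asarray(values[var], dtype=float) == f.param).astype(float)
            else:  # pragma: no cover - guarded at build time
                raise ValueError(f"unknown feature kind {f.kind!r}")
        return cols, clamp_total

    def variable_of_feature(self) -> list[tuple[str, ...]]:
        return [f.variables for f in self.features]


def build_features(
    background_values: dict[str, np.ndarray],
    classes: str | tuple[str, ...] = "LQ",
    n_knots: int = 10,
    categorical_legend: dict[str, list[int]] | None = None,
) -> FeatureSet:
    """Construct a :class:`FeatureSet` from background variable values.

    ``classes`` is a string or tuple over {L, Q, P, H, T}. Hinge/threshold
    knots sit at equally spaced interior background quantiles of each
    variable, strictly inside its range. Categorical variables (named in
    ``categorical_legend``) are expanded into per-class indicators regardless
    of the requested classes. Product features require >= 2 continuous
    variables; otherwise they silently contribute nothing.
    """
    cls = tuple(classes)
    unknown = set(cls) - set(FEATURE_CLASSES)
    if not cls:
        raise ValueError("at least one feature class is required")
    if unknown:
        raise ValueError(f"unknown feature classes {sorted(unknown)}")
    if ("H" in cls or "T" in cls) and n_knots < 1:
        raise ValueError("n_knots must be >= 1 for hinge/threshold features")
    categorical_legend = dict(categorical_legend or {})
    cont = [v for v in background_values if v not in categorical_legend]

    scaling: dict[str, tuple[float, float]] = {}
    quantiles: dict[str, np.ndarray] = {}
    for var in cont:
        x = np.asarray(background_values[var], dtype=float)
        scaling[var] = (float(x.min()), float(x.max()))
        if ("H" in cls or "T" in cls) and scaling[var][1] > scaling[var][0]:
            lo, hi = scaling[var]
            u = (np.clip(x, lo, hi) - lo) / (hi - lo)
            probs = np.arange(1, n_knots + 1) / (n_knots + 1)
            ks = np.unique(np.clip(np.quantile(u, probs), 1e-9, 1 - 1e-9))
            quantiles[var] = ks

    feats: list[Feature] = []
    for var in cont:
        if "L" in cls:
            feats.append(Feature(f"L:{var}", "linear", (var,)))
        if "Q" in cls:
            feats.append(Feature(f"Q:{var}", "quadratic", (var,)))
    if "P" in cls:
        for i, a in enumerate(cont):
            for b in cont[i + 1:]:
                feats.append(Feature(f"P:{a}*{b}", "product", (a, b)))
    for var in cont:
        for k in quantiles.get(var, []):
            if "H" in cls:
                feats.append(Feature(f"HF:{var}@{k:.6f}", "hinge_fwd", (var,), float(k)))
                feats.append(Feature(f"HR:{var}@{k:.6f}", "hinge_rev", (var,), float(k)))
            if "T" in cls:
                feats.append(Feature(f"T:{var}@{k:.6f}", "threshold", (var,), float(k)))
    for var, legend in categorical_legend.items():
        for code in legend:
            feats.append(Feature(f"C:{var}={code}", "categorical", (var,), float(code)))

    return FeatureSet(features=feats, scaling=scaling,
                      categorical_legend=categorical_legend, classes=cls)
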