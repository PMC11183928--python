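"""Collinearity screening of candidate environmental predictors.

Pairwise Pearson correlations are computed across grid cells; when any pair
of kept layers exceeds the absolute-correlation threshold (default |r| > 0.7)
the member with the larger mean absolute correlation to the remaining layers
is eliminated, greedily, until the kept set is threshold-feasible. Layers such
as elevation and categorical land cover can be exempted via ``keep_always``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import EnvStack

__all__ = ["CorrMatrix", "pearson_matrix", "select_variables"]


@dataclass
class CorrMatrix:
    """Symmetric Pearson correlation matrix over named layers."""

    matrix: pd.DataFrame
    flagged_zero_variance: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return list(self.matrix.index)

    def r(self, a: str, b: str) -> float:
        return float(self.matrix.loc[a, b])


def pearson_matrix(
    env: EnvStack,
    layer_names: list[str] | None = None,
    sample_cells: int | None = None,
    seed: int = 0,
) -> CorrMatrix:
    """Pearson product-moment correlations between continuous layers.

    Computed over all valid cells by default, or a seeded random subsample of
    ``sample_cells`` cells for very large grids. Zero-variance layers get NaN
    correlations and are flagged.
    """
    if layer_names is None:
        layer_names = env.continuous_names
    bad = [n for n in layer_names if n in env.categorical]
    if bad:
        raise ValueError(f"categorical layers cannot be screened: {bad}")
    flat = env.flat_values()
    n_cells = len(next(iter(flat.values()))) if flat else 0
    if n_cells < 3:
        raise ValueError("need at least 3 valid cells to estimate correlations")
    idx = np.arange(n_cells)
    if sample_cells is not None and sample_cells < n_cells:
        idx = np.random.default_rng(seed).choice(n_cells, size=sample_cells, replace=False)
    data = np.stack([flat[n][idx] for n in layer_names])
    sd = data.std(axis=1)
    flagged = [layer_names[i] for i in np.flatnonzero(sd == 0)]
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(data)
    mat = np.atleast_2d(mat)
    np.fill_diagonal(mat, 1.0)
    df = pd.DataFrame(mat, index=layer_names, columns=layer_names)
    return CorrMatrix(matrix=df, flagged_zero_variance=flagged)


def select_variables(
    corr: CorrMatrix,
    threshold: float = 0.7,
    keep_always: list[str] | None = None,
) -> list[str]:
    """Greedy elimination of collinear layers.

    While any kept pair has |r| > threshold, the member of the worst offending
    pair with the larger mean absolute correlation to all other kept layers is
    dropped (tie: drop the later layer in input order). ``keep_always`` layers
    are never dropped; if they violate the threshold among themselves an error
    lists the offending pairs.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    keep_always = list(keep_always or [])
    names = corr.names
    missing = [n for n in keep_always if n not in names]
    protected = set(keep_always) - set(missing)  # keep_always not in the matrix is vacuous
    abs_r = corr.matrix.abs()

    offenders = [
        (a, b) for i, a in enumerate(keep_always) for b in keep_always[i + 1:]
        if a in names and b in names and abs_r.loc[a, b] > threshold
    ]
    if offenders:
        raise ValueError(f"keep_always layers violate the threshold: {offenders}")

    kept = list(names)
    while True:
        sub = abs_r.loc[kept, kept].to_numpy(dtype=float)
        np.fill_diagonal(sub, 0.0)
        sub = np.nan_to_num(sub, nan=0.0)
        worst = sub.max()
        if worst <= threshold:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        a, b = kept[i], kept[j]
        candidates = [n for n in (a, b) if n not in protected]
        if not candidates:
            raise ValueError(f"protected pair ({a}, {b}) exceeds the threshold")
        if len(candidates) == 1:
            drop = candidates[0]
        else:
            n_others = max(len(kept) - 1, 1)
            mean_a = sub[i].sum() / n_others
            mean_b = sub[j].sum() / n_others
            if mean_a > mean_b:
                drop = a
            elif mean_b > mean_a:
                drop = b
            else:  # tie: drop the later layer in input order
                drop = b if names.index(b) > names.index(a) else a
        kept.remove(drop)
    return kept
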