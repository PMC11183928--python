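"""Virtual-species simulator: synthetic landscapes, species, records, reserves.

Every downstream stage of the pipeline (occurrence cleaning, collinearity
screening, niche-model fitting, stacking, gap analysis) can be exercised with
no external data by generating

* an environmental stack of spatially autocorrelated continuous layers with
  controllable pairwise correlation plus one categorical layer,
* virtual species whose true habitat suitability is a known logistic function
  of the layers,
* presence records sampled from that truth (optionally through a sampling-bias
  surface) with coordinates jittered inside the chosen cell, and
* protected-area masks hitting a target coverage fraction.

All operations are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import EnvStack, GridSpec, PAMask

__all__ = [
    "LayerSpec",
    "TrueSuitability",
    "make_landscape",
    "make_virtual_species",
    "sample_occurrences",
    "make_protected_areas",
    "assign_traits",
    "TRAIT_PROPORTIONS",
]

#: Default trait mix for virtual communities: the residency, diet, national
#: protection-class and IUCN proportions of a 312-species regional avifauna
#: (82 resident / 230 migratory; 196 carnivorous / 105 omnivorous /
#: 11 herbivorous; 10 class-I / 52 class-II; 2 CR / 6 EN / 17 NT / 17 VU).
TRAIT_PROPORTIONS: dict[str, dict[str, float]] = {
    "residency": {"resident": 82 / 312, "migratory": 230 / 312},
    "diet": {"carnivorous": 196 / 312, "omnivorous": 105 / 312, "herbivorous": 11 / 312},
    "china_class": {"I": 10 / 312, "II": 52 / 312, "none": 250 / 312},
    "iucn": {"CR": 2 / 312, "EN": 6 / 312, "NT": 17 / 312, "VU": 17 / 312, "LC": 270 / 312},
}


@dataclass(frozen=True)
class LayerSpec:
    """Request for one synthetic layer.

    ``kind`` is ``"continuous"`` or ``"categorical"``; ``rho`` is the target
    Pearson correlation to the first (reference) layer and is ignored for the
    reference layer itself and for categorical layers.
    """

    name: str
    kind: str = "continuous"
    rho: float = 0.0
    n_classes: int = 5

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")


@dataclass
class TrueSuitability:
    """Known suitability surface of a virtual species (simulation ground truth)."""

    env: EnvStack
    surface: np.ndarray  # in [0, 1]; NaN at nodata
    coefficients: dict[str, object]
    link: str = "logistic"
    species: str = "virtual_species"

    def flat(self) -> np.ndarray:
        return self.surface[self.env.valid_mask()]


def _smooth_field(rng: np.lib.mixins.NDArrayOperatorsMixin, shape: tuple[int, int],
                  n_bumps: int, bandwidth: float) -> np.ndarray:
    """Spatially autocorrelated field as a sum of random Gaussian bumps.

    Coordinates are normalized to the unit square; bandwidth is a fraction of
    that square. The field is standardized to mean 0, sd 1 over all cells.
    """
    n_rows, n_cols = shape
    yy, xx = np.meshgrid(
        (np.arange(n_rows) + 0.5) / max(n_rows, 1),
        (np.arange(n_cols) + 0.5) / max(n_cols, 1),
        indexing="ij",
    )
    cx = rng.uniform(0.0, 1.0, n_bumps)
    cy = rng.uniform(0.0, 1.0, n_bumps)
    amp = rng.normal(0.0, 1.0, n_bumps)
    bw = bandwidth * rng.uniform(0.6, 1.4, n_bumps)
    f = np.zeros(shape, dtype=float)
    for k in range(n_bumps):
        f += amp[k] * np.exp(-((xx - cx[k]) ** 2 + (yy - cy[k]) ** 2) / (2.0 * bw[k] ** 2))
    sd = f.std()
    if sd > 0:
        f = (f - f.mean()) / sd
    else:
        f = f - f.mean()
    return f


def _correlate_exact(ref: np.ndarray, raw: np.ndarray, rho: float) -> np.ndarray:
    """Blend ``raw`` with ``ref`` so the sample correlation to ``ref`` is rho.

    The independent field is first orthogonalized against the reference and
    re-standardized, making the realized sample correlation exactly the target
    (up to floating point) rather than merely its expectation.
    """
    if ref.size < 2 or ref.std() == 0:
        return raw
    z1 = (ref - ref.mean()) / ref.std()
    resid = raw - (raw * z1).mean() / (z1 * z1).mean() * z1
    sd = resid.std()
    if sd == 0:
        return raw
    z2 = (resid - resid.mean()) / sd
    return rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * z2


def make_landscape(
    n_rows: int,
    n_cols: int,
    layer_spec: list[LayerSpec | tuple],
    seed: int,
    grid: GridSpec | None = None,
    n_bumps: int = 150,
    bandwidth: float = 0.08,
) -> EnvStack:
    """Generate a synthetic environmental stack.

    Continuous layers are smooth (spatially autocorrelated) standardized
    fields; layers after the first are blended with the first to realize the
    requested pairwise Pearson correlation. The categorical layer is produced
    by quantile-thresholding its own smooth field into ``n_classes`` codes.
    """
    specs = [s if isinstance(s, LayerSpec) else LayerSpec(*s) for s in layer_spec]
    if grid is None:
        grid = GridSpec(n_rows=n_rows, n_cols=n_cols)
    rng = np.random.default_rng(seed)
    layers: dict[str, np.ndarray] = {}
    categorical: dict[str, list[int]] = {}
    ref: np.ndarray | None = None
    for spec in specs:
        f = _smooth_field(rng, grid.shape, n_bumps, bandwidth)
        if spec.kind == "continuous":
            if ref is None:
                ref = f
            else:
                f = _correlate_exact(ref.ravel(), f.ravel(), spec.rho).reshape(grid.shape)
            layers[spec.name] = f
        else:
            qs = np.quantile(f, np.linspace(0, 1, spec.n_classes + 1)[1:-1])
            layers[spec.name] = np.digitize(f, qs).astype(float)
            categorical[spec.name] = list(range(spec.n_classes))
    return EnvStack(grid=grid, layers=layers, categorical=categorical)


def _standardized_layers(env: EnvStack) -> dict[str, np.ndarray]:
    out = {}
    ok = env.valid_mask()
    for name in env.continuous_names:
        arr = env.layers[name]
        mu = arr[ok].mean()
        sd = arr[ok].std()
        out[name] = (arr - mu) / (sd if sd > 0 else 1.0)
    return out


def make_virtual_species(
    env: EnvStack,
    coefficients: dict[str, object],
    link: str = "logistic",
    seed: int = 0,
    species: str = "virtual_species",
) -> TrueSuitability:
    """Define a virtual species with a known suitability function.

    ``coefficients`` maps layer names to weights applied to internally
    standardized layer values. ``"<layer>^2"`` keys add quadratic terms;
    ``"intercept"`` shifts the linear predictor. Weights on a categorical
    layer must be a per-class mapping ``{code: weight}``.
    """
    if link != "logistic":
        raise ValueError(f"unsupported link {link!r}")
    std = _standardized_layers(env)
    eta = np.zeros(env.grid.shape, dtype=float)
    eta += float(coefficients.get("intercept", 0.0))
    for key, w in coefficients.items():
        if key == "intercept":
            continue
        base = key[:-2] if key.endswith("^2") else key
        if base not in env.layers:
            raise KeyError(f"coefficient references unknown layer {base!r}")
        if base in env.categorical:
            if not isinstance(w, dict):
                raise TypeError(
                    f"layer {base!r} is categorical: supply a per-class weight table, not a scalar"
                )
            vals = env.layers[base]
            for code, cw in w.items():
                eta += float(cw) * (vals == float(code))
        else:
            z = std[base]
            eta += float(w) * (z ** 2 if key.endswith("^2") else z)
    surface = 1.0 / (1.0 + np.exp(-eta))
    surface = np.where(env.valid_mask(), surface, np.nan)
    return TrueSuitability(env=env, surface=surface, coefficients=dict(coefficients),
                           link=link, species=species)


_OCCURRENCE_COLUMNS = ["species", "longitude", "latitude", "date",
                       "residency", "diet", "china_class", "iucn"]


def sample_occurrences(
    truth: TrueSuitability,
    n_records: int,
    seed: int,
    bias_surface: np.ndarray | None = None,
    traits: dict[str, str] | None = None,
    date_window: tuple[str, str] = ("2013-01-01", "2023-12-31"),
) -> pd.DataFrame:
    """Sample presence records from a virtual species.

    Cells are drawn with probability proportional to suitability x bias
    (uniform bias if absent); each record's coordinates are jittered uniformly
    within its cell. Observation dates are drawn uniformly from the window.
    """
    if n_records < 0:
        raise ValueError("n_records must be non-negative")
    env = truth.env
    grid = env.grid
    rng = np.random.default_rng(seed)
    p = np.nan_to_num(truth.surface, nan=0.0).ravel().astype(float)
    if bias_surface is not None:
        bias = np.asarray(bias_surface, dtype=float)
        if bias.shape != grid.shape:
            raise ValueError("bias surface shape does not match grid")
        p = p * np.clip(bias.ravel(), 0.0, None)
    if n_records == 0:
        return pd.DataFrame(columns=_OCCURRENCE_COLUMNS)
    total = p.sum()
    if total <= 0:
        raise ValueError("suitability x bias is zero everywhere: no valid support")
    p = p / total
    cells = rng.choice(p.size, size=n_records, p=p)
    rows, cols = np.unravel_index(cells, grid.shape)
    lon = grid.x_origin + (cols + rng.uniform(0, 1, n_records)) * grid.cell_size
    lat = grid.y_origin - (rows + rng.uniform(0, 1, n_records)) * grid.cell_size
    d0 = _dt.date.fromisoformat(date_window[0]).toordinal()
    d1 = _dt.date.fromisoformat(date_window[1]).toordinal()
    dates = [_dt.date.fromordinal(int(o)).isoformat() for o in rng.integers(d0, d1 + 1, n_records)]
    traits = traits or {}
    df = pd.DataFrame(
        {
            "species": truth.species,
            "longitude": lon,
            "latitude": lat,
            "date": dates,
            "residency": traits.get("residency", "resident"),
            "diet": traits.get("diet", "carnivorous"),
            "china_class": traits.get("china_class", "none"),
            "iucn": traits.get("iucn", "LC"),
        }
    )
    return df[_OCCURRENCE_COLUMNS]


def make_protected_areas(
    env: EnvStack,
    target_fraction: float,
    n_patches: int = 5,
    seed: int = 0,
    tolerance: float = 0.02,
    max_attempts: int = 200,
) -> PAMask:
    """Random reserve network: union of rectangular patches grown/shrunk until
    the covered fraction is within ``tolerance`` of the target."""
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    grid = env.grid
    shape = grid.shape
    if target_fraction == 0.0:
        return PAMask(grid=grid, mask=np.zeros(shape, dtype=bool))
    if target_fraction == 1.0:
        return PAMask(grid=grid, mask=np.ones(shape, dtype=bool))
    rng = np.random.default_rng(seed)
    cy = rng.uniform(0, shape[0], n_patches)
    cx = rng.uniform(0, shape[1], n_patches)
    aspect = rng.uniform(0.5, 2.0, n_patches)
    rr, cc = np.meshgrid(np.arange(shape[0]) + 0.5, np.arange(shape[1]) + 0.5, indexing="ij")

    def coverage(scale: float) -> np.ndarray:
        half = scale * np.sqrt(shape[0] * shape[1] * target_fraction / n_patches) / 2.0
        mask = np.zeros(shape, dtype=bool)
        for k in range(n_patches):
            hy, hx = half * aspect[k], half / aspect[k]
            mask |= (np.abs(rr - cy[k]) <= hy) & (np.abs(cc - cx[k]) <= hx)
        return mask

    lo, hi = 1e-3, 8.0
    best, best_err = None, np.inf
    for _ in range(max_attempts):
        mid = 0.5 * (lo + hi)
        mask = coverage(mid)
        frac = mask.mean()
        err = abs(frac - target_fraction)
        if err < best_err:
            best, best_err = mask, err
        if err <= tolerance:
            return PAMask(grid=grid, mask=mask)
        if frac < target_fraction:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"could not reach PA coverage {target_fraction:.3f} +/- {tolerance}: "
        f"best achieved {float(best.mean()):.3f}"
    )


def assign_traits(
    species: list[str],
    seed: int,
    proportions: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Assign residency/diet/protection/IUCN labels to a species roster.

    Labels are dealt deterministically to match the configured proportions as
    closely as integer counts allow (largest-remainder apportionment), then
    shuffled across species with the seed.
    """
    props = proportions or TRAIT_PROPORTIONS
    rng = np.random.default_rng(seed)
    n = len(species)
    out = {"species": list(species)}
    for trait, levels in props.items():
        targets = {lvl: p * n for lvl, p in levels.items()}
        counts = {lvl: int(np.floor(t)) for lvl, t in targets.items()}
        short = n - sum(counts.values())
        by_remainder = sorted(levels, key=lambda lvl: targets[lvl] - counts[lvl], reverse=True)
        for lvl in by_remainder[:short]:
            counts[lvl] += 1
        labels = np.repeat(list(counts.keys()), list(counts.values()))
        rng.shuffle(labels)
        out[trait] = labels[:n]
    return pd.DataFrame(out)
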