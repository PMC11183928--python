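"""End-to-end pipeline: simulate (or load) -> prep -> screen -> fit -> stack
-> hotspots -> gap report, under one config with reproducible seeding.

Per-species randomness is drawn from streams derived from the master seed and
a stable hash of the species name, so results are independent of the order in
which species are processed. Per-species failures (for example a species
whose records collapse under thinning) are recorded in the manifest and
skipped rather than aborting the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .evaluation import auc, maxsss_threshold, tss_at_threshold
from .grids import EnvStack, PAMask, cell_size_km, write_ascii_grid
from .hotspots import (
    HotspotClasses,
    cell_area_km2,
    classify_richness,
    composition_summary,
    gap_analysis,
    jenks_breaks,
)
from .maxent import predict_suitability
from .occurrences import prepare_occurrences
from .screening import pearson_matrix, select_variables
from .simulate import (
    LayerSpec,
    assign_traits,
    make_landscape,
    make_protected_areas,
    make_virtual_species,
    sample_occurrences,
)
from .stacking import binarize, stack_richness, subgroup_stack
from .tuning import TuningGrid, tune

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "species_seed"]

DEFAULT_LAYERS = (
    LayerSpec("bio1", "continuous", 0.0),
    LayerSpec("bio2", "continuous", 0.3),
    LayerSpec("bio9", "continuous", 0.5),
    LayerSpec("bio12", "continuous", -0.3),
    LayerSpec("bio13", "continuous", 0.4),
    LayerSpec("ele", "continuous", 0.1),
    LayerSpec("LC", "categorical", 0.0, n_classes=5),
)


@dataclass
class RunConfig:
    """All knobs of a pipeline run. Every stochastic stage is seeded."""

    seed: int = 0
    out_dir: str | None = None
    # simulation
    n_rows: int = 40
    n_cols: int = 40
    n_species: int = 10
    n_records_per_species: int = 150
    pa_fraction: float = 0.2
    pa_patches: int = 5
    layers: tuple = DEFAULT_LAYERS
    # occurrence prep
    min_records: int = 15
    dedup_arcmin: float | None = 2.5
    thin_km: float | None = None  # None -> one model-grid cell size
    date_window: tuple[str, str] = ("2013-01-01", "2023-12-31")
    # screening
    corr_threshold: float = 0.7
    keep_always: tuple[str, ...] = ("ele", "LC")
    # model selection
    feature_combinations: tuple[str, ...] = ("L", "LQ")
    rms: tuple[float, ...] = (1.0,)
    folds: int = 5
    omission_cap: float = 0.05
    n_knots: int = 10
    max_iter: int = 500
    tol: float = 1e-5
    # stacking / hotspots
    binarize_rule: str = "maxsss"  # maxsss | fixed | p10
    fixed_threshold: float = 0.5
    class_intervals: tuple | None = None  # None -> natural breaks on the data
    n_hotspot_classes: int = 3


@dataclass
class RunManifest:
    """What a run produced: counts, per-species choices, artifact checksums."""

    config: dict
    prep_stages: list[dict] = field(default_factory=list)
    kept_variables: list[str] = field(default_factory=list)
    species: dict[str, dict] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    class_bounds: list[tuple[float, float]] = field(default_factory=list)
    gap_table: list[dict] = field(default_factory=list)
    composition: list[dict] = field(default_factory=list)
    artifacts: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, Path):
                return str(o)
            raise TypeError(f"not JSON-serializable: {type(o)}")

        return json.dumps(asdict(self), indent=2, default=default)


def species_seed(master_seed: int, species: str, stream: str = "") -> int:
    """Stable per-species seed below 2^31, independent of processing order."""
    digest = hashlib.sha256(f"{master_seed}:{species}:{stream}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _checksum(arr: np.ndarray) -> str:
    clean = np.nan_to_num(np.asarray(arr, dtype=float), nan=-9999.0)
    return hashlib.sha256(np.ascontiguousarray(clean).tobytes()).hexdigest()


@dataclass
class PipelineResult:
    """In-memory artifacts of a run (the manifest carries the summary)."""

    manifest: RunManifest
    env: EnvStack
    pa: PAMask
    occurrences: pd.DataFrame
    traits: pd.DataFrame
    richness: dict  # subgroup label -> RichnessMap
    class_raster: np.ndarray | None
    classes: HotspotClasses | None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full stacked-SDM workflow on a simulated community."""
    cfg = config

    # --- landscape, reserves, virtual community --------------------------
    env = make_landscape(cfg.n_rows, cfg.n_cols, list(cfg.layers), seed=cfg.seed)
    pa = make_protected_areas(env, cfg.pa_fraction, n_patches=cfg.pa_patches,
                              seed=cfg.seed + 1)
    species_names = [f"species_{i:03d}" for i in range(cfg.n_species)]
    traits = assign_traits(species_names, seed=cfg.seed + 2)
    trait_map = traits.set_index("species").to_dict("index")

    continuous = env.continuous_names
    records = []
    truths = {}
    for name in species_names:
        s_rng = np.random.default_rng(species_seed(cfg.seed, name, "truth"))
        # Each virtual species responds to 2-3 randomly chosen layers.
        n_resp = int(s_rng.integers(2, 4))
        chosen = s_rng.choice(continuous, size=n_resp, replace=False)
        coef = {"intercept": float(s_rng.normal(-1.0, 0.5))}
        for lay in chosen:
            coef[str(lay)] = float(s_rng.normal(0.0, 1.5))
        truth = make_virtual_species(env, coef, seed=0, species=name)
        truths[name] = truth
        rec = sample_occurrences(
            truth,
            cfg.n_records_per_species,
            seed=species_seed(cfg.seed, name, "sample"),
            traits=trait_map[name],
            date_window=cfg.date_window,
        )
        records.append(rec)
    occurrences = pd.concat(records, ignore_index=True)

    # --- occurrence prep --------------------------------------------------
    grid = env.grid
    extent = (
        grid.x_origin,
        grid.y_origin - grid.n_rows * grid.cell_size,
        grid.x_origin + grid.n_cols * grid.cell_size,
        grid.y_origin,
    )
    thin_km = cfg.thin_km if cfg.thin_km is not None else cell_size_km(grid)
    prepped, prep_log = prepare_occurrences(
        occurrences,
        extent,
        date_window=cfg.date_window,
        min_records=cfg.min_records,
        dedup_arcmin=cfg.dedup_arcmin,
        thin_km=thin_km,
        seed=cfg.seed + 3,
    )
    manifest = RunManifest(config={k: str(v) for k, v in asdict(cfg).items()})
    manifest.prep_stages = prep_log.stages
    surviving = sorted(prepped["species"].unique())
    if not surviving:
        raise RuntimeError("no species survived occurrence preparation")

    # --- predictor screening ---------------------------------------------
    screen_names = [n for n in continuous if n not in cfg.keep_always]
    corr = pearson_matrix(env, screen_names)
    kept = select_variables(corr, threshold=cfg.corr_threshold)
    kept += [n for n in cfg.keep_always if n in env.layers]
    manifest.kept_variables = kept
    legend = {n: env.categorical[n] for n in kept if n in env.categorical}

    background_values = {n: env.layers[n][env.valid_mask()] for n in kept}
    ok = env.valid_mask()

    # --- per-species model fitting and binarization -----------------------
    grid_spec = TuningGrid(feature_combinations=cfg.feature_combinations, rms=cfg.rms)
    binary_maps = []
    for name in surviving:
        sub = prepped[prepped["species"] == name]
        try:
            rows, cols = grid.point_to_cell(sub["longitude"].to_numpy(),
                                            sub["latitude"].to_numpy())
            pres_values = {n: env.layers[n][rows, cols] for n in kept}
            result = tune(
                pres_values,
                background_values,
                grid=grid_spec,
                k=min(cfg.folds, len(sub)),
                omission_cap=cfg.omission_cap,
                seed=species_seed(cfg.seed, name, "cv"),
                categorical_legend=legend,
                n_knots=cfg.n_knots,
                max_iter=cfg.max_iter,
                tol=cfg.tol,
            )
            fit = result.fit
            suit = predict_suitability(fit, env, scale="logistic", species=name)
            pres_scores = suit.values[rows, cols]
            back_scores = suit.values[ok]
            if cfg.binarize_rule == "maxsss":
                threshold = maxsss_threshold(pres_scores, back_scores)
            elif cfg.binarize_rule == "p10":
                threshold = float(np.percentile(pres_scores, 10.0))
            else:
                threshold = cfg.fixed_threshold
            ev = tss_at_threshold(pres_scores, back_scores, threshold)
            bm = binarize(suit, threshold)
            binary_maps.append(bm)
            spearman = float(spearmanr(suit.values[ok], truths[name].flat()).statistic)
            manifest.species[name] = {
                "n_records": int(len(sub)),
                "fc": result.fc,
                "rm": result.rm,
                "omission_feasible": bool(result.feasible),
                "threshold": float(threshold),
                "threshold_rule": cfg.binarize_rule,
                "auc": ev.auc,
                "tss": ev.tss,
                "band": ev.band,
                "spearman_vs_truth": spearman,
                "k_active": fit.n_active,
            }
        except Exception as exc:  # per-species failures are recorded, not fatal
            manifest.failures[name] = f"{type(exc).__name__}: {exc}"
    if not binary_maps:
        raise RuntimeError("model fitting failed for every species")

    # --- stacking ----------------------------------------------------------
    shape = grid.shape
    richness = {"all": stack_richness(binary_maps, "all", shape=shape)}
    selectors = {
        "resident": lambda t: t["residency"] == "resident",
        "migratory": lambda t: t["residency"] == "migratory",
        "carnivorous": lambda t: t["diet"] == "carnivorous",
        "omnivorous": lambda t: t["diet"] == "omnivorous",
        "herbivorous": lambda t: t["diet"] == "herbivorous",
        "china_protected": lambda t: t["china_class"] != "none",
        "iucn_listed": lambda t: t["iucn"] not in ("LC",),
    }
    for label, sel in selectors.items():
        richness[label] = subgroup_stack(binary_maps, trait_map, sel, label, shape=shape)

    # --- hotspots and gap analysis -----------------------------------------
    classes = None
    class_raster = None
    total = richness["all"]
    positive = total.flat_positive()
    if cfg.class_intervals is not None:
        classes = HotspotClasses(bounds=[tuple(b) for b in cfg.class_intervals])
    else:
        distinct = np.unique(positive)
        if distinct.size >= cfg.n_hotspot_classes:
            classes = jenks_breaks(positive, cfg.n_hotspot_classes)
    if classes is not None:
        class_raster = classify_richness(total, classes)
        areas = cell_area_km2(grid)
        gap = gap_analysis(class_raster, classes, pa, areas)
        manifest.class_bounds = [list(b) for b in classes.bounds]
        manifest.gap_table = gap.table.to_dict("records")

    comp = composition_summary(traits, denominator=len(traits))
    manifest.composition = comp.to_dict("records")

    # --- checksums and optional artifact output ----------------------------
    for label, rmap in richness.items():
        manifest.checksums[f"richness_{label}"] = _checksum(rmap.values)
    if class_raster is not None:
        manifest.checksums["class_raster"] = _checksum(class_raster)
    manifest.checksums["pa_mask"] = _checksum(pa.mask.astype(float))

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        env.write_dir(out / "layers")
        occurrences.to_csv(out / "occurrences_raw.csv", index=False)
        prepped.to_csv(out / "occurrences_prepped.csv", index=False)
        traits.to_csv(out / "traits.csv", index=False)
        for label, rmap in richness.items():
            write_ascii_grid(out / f"richness_{label}.asc", rmap.values, grid)
        write_ascii_grid(out / "pa_mask.asc", pa.mask.astype(float), grid)
        if class_raster is not None:
            write_ascii_grid(out / "hotspot_classes.asc", class_raster.astype(float), grid)
        comp.to_csv(out / "composition.csv", index=False)
        if manifest.gap_table:
            pd.DataFrame(manifest.gap_table).to_csv(out / "gap_report.csv", index=False)
        (out / "manifest.json").write_text(manifest.to_json())
        manifest.artifacts = {p.name: str(p) for p in sorted(out.glob("*"))}

    return PipelineResult(
        manifest=manifest,
        env=env,
        pa=pa,
        occurrences=occurrences,
        traits=traits,
        richness=richness,
        class_raster=class_raster,
        classes=classes,
    )
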