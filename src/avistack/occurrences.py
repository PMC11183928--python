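"""Occurrence-record cleaning, grid deduplication and spatial rarefaction.

Raw presence tables are filtered in stages before model fitting:

1. :func:`clean_records` drops rows with missing/invalid coordinates, rows
   outside the study extent or observation window (default 2013-2023), and
   exact duplicates on (species, longitude, latitude, date).
2. :func:`grid_dedup` keeps one randomly chosen record per species per grid
   cell (default 2.5 arc-minutes) to damp sampling-intensity bias.
3. :func:`thin_spatial` enforces a minimum great-circle distance between any
   two records of a species, keeping as many records as the heuristic finds.
4. :func:`filter_min_records` drops species below the minimum sample size for
   distribution modelling (default 15 records).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import haversine_km

__all__ = [
    "clean_records",
    "filter_min_records",
    "grid_dedup",
    "thin_spatial",
    "PrepLog",
    "prepare_occurrences",
]

BoundingBox = tuple[float, float, float, float]  # lon_min, lat_min, lon_max, lat_max


def clean_records(
    raw: pd.DataFrame,
    extent: BoundingBox,
    date_window: tuple[str, str] = ("2013-01-01", "2023-12-31"),
) -> pd.DataFrame:
    """Remove invalid, out-of-extent, out-of-window and duplicate rows.

    Duplicates are exact matches on (species, longitude, latitude, date); the
    first occurrence survives. Input row order is preserved.
    """
    lon_min, lat_min, lon_max, lat_max = extent
    if lon_min > lon_max or lat_min > lat_max:
        raise ValueError("malformed extent")
    df = raw.copy()
    if df.empty:
        return df
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    ok = np.isfinite(lon) & np.isfinite(lat)
    ok &= (lon >= lon_min) & (lon <= lon_max) & (lat >= lat_min) & (lat <= lat_max)
    ok &= lon.between(-180, 180) & lat.between(-90, 90)
    dates = pd.to_datetime(df["date"], errors="coerce")
    ok &= dates.notna() & (dates >= pd.Timestamp(date_window[0])) & (dates <= pd.Timestamp(date_window[1]))
    ok &= df["species"].astype(str).str.len() > 0
    df = df[ok.to_numpy(dtype=bool)]
    df = df[~df.duplicated(subset=["species", "longitude", "latitude", "date"], keep="first")]
    return df


def filter_min_records(table: pd.DataFrame, min_n: int = 15) -> pd.DataFrame:
    """Drop every species with fewer than ``min_n`` records."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    if table.empty:
        return table.copy()
    counts = table.groupby("species")["species"].transform("size")
    return table[counts >= min_n]


def grid_dedup(
    table: pd.DataFrame,
    cell_size_arcmin: float = 2.5,
    seed: int = 0,
    anchor: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Retain one record per species per grid cell, chosen uniformly at random.

    Cells are half-open intervals of ``cell_size_arcmin`` anchored at the
    north-west corner of the table's extent (or an explicit anchor).
    """
    if cell_size_arcmin <= 0:
        raise ValueError("cell size must be positive")
    if table.empty:
        return table.copy()
    cs = cell_size_arcmin / 60.0
    lon = table["longitude"].to_numpy(dtype=float)
    lat = table["latitude"].to_numpy(dtype=float)
    if anchor is None:
        anchor = (float(lon.min()), float(lat.max()))
    col = np.floor((lon - anchor[0]) / cs).astype(int)
    row = np.floor((anchor[1] - lat) / cs).astype(int)
    rng = np.random.default_rng(seed)
    # Seeded random priority per row; the max-priority record in each
    # (species, cell) group survives -> uniform choice within the group.
    prio = rng.random(len(table))
    key = pd.DataFrame({"species": table["species"].to_numpy(), "row": row, "col": col, "prio": prio},
                       index=table.index)
    keep = key.groupby(["species", "row", "col"])["prio"].transform("max") == key["prio"]
    return table[keep.to_numpy(dtype=bool)]


def _thin_one(lon: np.ndarray, lat: np.ndarray, d_km: float, n_attempts: int,
              rng: np.random.Generator) -> np.ndarray:
    """Indices of a large subset with all pairwise distances >= d_km.

    Iteratively deletes the point with the most conflicting neighbours (ties
    broken uniformly at random), restarted ``n_attempts`` times; for small
    inputs an exact maximum independent set is solved as well, so the result
    is optimal whenever n <= 15.
    """
    n = len(lon)
    if n <= 1:
        return np.arange(n)
    dm = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    conflict = (dm < d_km) & ~np.eye(n, dtype=bool)
    if not conflict.any():
        return np.arange(n)

    best: np.ndarray | None = None
    for _ in range(max(1, n_attempts)):
        alive = np.ones(n, dtype=bool)
        c = conflict.copy()
        while True:
            deg = c[np.ix_(alive, alive)].sum(axis=1)
            if deg.max(initial=0) == 0:
                break
            alive_idx = np.flatnonzero(alive)
            worst = alive_idx[np.flatnonzero(deg == deg.max())]
            drop = rng.choice(worst)
            alive[drop] = False
        idx = np.flatnonzero(alive)
        if best is None or len(idx) > len(best):
            best = idx

    if n <= 15:
        exact = _max_independent_set(conflict)
        if len(exact) > len(best):
            best = exact
    return best


def _max_independent_set(conflict: np.ndarray) -> np.ndarray:
    """Exact maximum independent set by branch and bound on bitmasks."""
    n = conflict.shape[0]
    nbr = [0] * n
    for i in range(n):
        for j in range(n):
            if conflict[i, j]:
                nbr[i] |= 1 << j
    best_mask = 0
    best_size = 0

    def rec(cand: int, chosen: int, size: int) -> None:
        nonlocal best_mask, best_size
        if size + bin(cand).count("1") <= best_size:
            return
        if cand == 0:
            if size > best_size:
                best_size, best_mask = size, chosen
            return
        v = (cand & -cand).bit_length() - 1
        rec(cand & ~(1 << v) & ~nbr[v], chosen | (1 << v), size + 1)
        rec(cand & ~(1 << v), chosen, size)

    rec((1 << n) - 1, 0, 0)
    return np.array([i for i in range(n) if best_mask >> i & 1], dtype=int)


def thin_spatial(
    table: pd.DataFrame,
    thin_distance_km: float,
    n_attempts: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Spatial rarefaction: per species, keep a subset of records whose
    pairwise great-circle distances are all >= ``thin_distance_km``."""
    if thin_distance_km < 0:
        raise ValueError("thin distance must be non-negative")
    if table.empty or thin_distance_km == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    kept_parts = []
    for _, sub in table.groupby("species", sort=False):
        idx = _thin_one(
            sub["longitude"].to_numpy(dtype=float),
            sub["latitude"].to_numpy(dtype=float),
            thin_distance_km,
            n_attempts,
            rng,
        )
        kept_parts.append(sub.iloc[np.sort(idx)])
    out = pd.concat(kept_parts) if kept_parts else table.iloc[:0]
    return out.sort_index()


@dataclass
class PrepLog:
    """Per-stage record and species counts of an occurrence-prep run."""

    stages: list[dict] = field(default_factory=list)
    flagged_species: list[str] = field(default_factory=list)

    def add(self, stage: str, table: pd.DataFrame) -> None:
        self.stages.append(
            {"stage": stage, "n_records": int(len(table)),
             "n_species": int(table["species"].nunique()) if len(table) else 0}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def prepare_occurrences(
    raw: pd.DataFrame,
    extent: BoundingBox,
    date_window: tuple[str, str] = ("2013-01-01", "2023-12-31"),
    min_records: int = 15,
    dedup_arcmin: float | None = 2.5,
    thin_km: float | None = 1.0,
    n_attempts: int = 25,
    seed: int = 0,
) -> tuple[pd.DataFrame, PrepLog]:
    """Full cleaning funnel: clean -> grid dedup -> min-records -> thin.

    Species that fall below ``min_records`` only after thinning are flagged in
    the log rather than dropped.
    """
    log = PrepLog()
    log.add("input", raw)
    df = clean_records(raw, extent, date_window)
    log.add("clean", df)
    if dedup_arcmin:
        df = grid_dedup(df, dedup_arcmin, seed=seed)
        log.add("grid_dedup", df)
    df = filter_min_records(df, min_records)
    log.add("min_records", df)
    if thin_km:
        df = thin_spatial(df, thin_km, n_attempts=n_attempts, seed=seed + 1)
        log.add("thin", df)
        counts = df.groupby("species").size()
        log.flagged_species = sorted(counts[counts < min_records].index)
    return df, log
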