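"""Hotspot classification and protected-area gap accounting.

Positive richness values are classified into ordered levels (default
moderate / sub-hotspot / hotspot) either by Fisher-Jenks natural breaks —
the 1-D dynamic program minimizing total within-class sum of squared
deviations — or by fixed intervals supplied verbatim. Overlaying the class
raster with a protected-area mask yields, per class, the total area, the
protected area and percentage, and the unprotected (gap) area. Community
composition tables report per-group counts and percentages against a stated
denominator. All printed percentages round half-up to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .grids import GridSpec, PAMask
from .stacking import RichnessMap

__all__ = [
    "HotspotClasses",
    "GapReport",
    "round_half_up",
    "jenks_breaks",
    "classify_richness",
    "cell_area_km2",
    "gap_analysis",
    "gap_analysis_table",
    "composition_summary",
]

DEFAULT_CLASS_NAMES = ("moderate", "sub-hotspot", "hotspot")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at the given decimal, e.g. 0.125 -> 0.13."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class HotspotClasses:
    """Ordered, contiguous richness intervals with inclusive bounds."""

    bounds: list[tuple[float, float]]  # (lower, upper) inclusive, ascending
    names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.names):
            raise ValueError("one name per class interval is required")
        for (lo, hi) in self.bounds:
            if lo > hi:
                raise ValueError("malformed class interval")
        for (_, hi), (lo2, _) in zip(self.bounds, self.bounds[1:]):
            if lo2 <= hi:
                raise ValueError("class intervals must ascend without overlap")

    @property
    def n_classes(self) -> int:
        return len(self.bounds)


def jenks_breaks(values, n_classes: int = 3,
                 names: tuple[str, ...] = DEFAULT_CLASS_NAMES) -> HotspotClasses:
    """Fisher-Jenks natural breaks over positive richness values.

    Dynamic program minimizing the total within-class sum of squared
    deviations; zero values are excluded before classification. Class bounds
    are reported as the min/max data values of each class (inclusive).
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v) & (v > 0)]
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    distinct = np.unique(v)
    if distinct.size < n_classes:
        raise ValueError(
            f"need at least {n_classes} distinct positive values, got {distinct.size}"
        )
    # DP over distinct values weighted by multiplicity: identical values can
    # never straddle a break, so this is exact and much smaller than cell count.
    counts = np.array([np.sum(v == d) for d in distinct], dtype=float)
    x, w = distinct, counts
    n = x.size
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwx = np.concatenate([[0.0], np.cumsum(w * x)])
    cwx2 = np.concatenate([[0.0], np.cumsum(w * x * x)])

    def ss(i: int, j: int) -> float:
        """Within-class SS of values i..j-1 (half-open on distinct index)."""
        wt = cw[j] - cw[i]
        sx = cwx[j] - cwx[i]
        sx2 = cwx2[j] - cwx2[i]
        return sx2 - sx * sx / wt

    cost = np.full((n_classes + 1, n + 1), np.inf)
    back = np.zeros((n_classes + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, n_classes + 1):
        for j in range(c, n + 1):
            best, arg = np.inf, c - 1
            for i in range(c - 1, j):
                val = cost[c - 1, i] + ss(i, j)
                if val < best - 1e-12:
                    best, arg = val, i
            cost[c, j] = best
            back[c, j] = arg
    cuts = [n]
    j = n
    for c in range(n_classes, 0, -1):
        j = back[c, j]
        cuts.append(j)
    cuts = cuts[::-1]
    bounds = [(float(x[cuts[c]]), float(x[cuts[c + 1] - 1])) for c in range(n_classes)]
    return HotspotClasses(bounds=bounds, names=names)


def classify_richness(richness: RichnessMap, classes: HotspotClasses,
                      clip_above: bool = True) -> np.ndarray:
    """Class index per cell (0-based); -1 for zero, unclassified or nodata.

    Values above the top interval are clipped into the top class by default
    (relevant when fixed intervals are supplied); with ``clip_above=False``
    they stay unclassified.
    """
    vals = richness.values
    out = np.full(vals.shape, -1, dtype=int)
    finite = np.isfinite(vals)
    for ci, (lo, hi) in enumerate(classes.bounds):
        sel = finite & (vals >= lo) & (vals <= hi) & (vals > 0)
        out[sel] = ci
    if clip_above:
        top = classes.bounds[-1][1]
        out[finite & (vals > top)] = classes.n_classes - 1
    return out


def cell_area_km2(grid: GridSpec, latitude: float | None = None) -> np.ndarray:
    """Area in km^2 of every cell (per-row for geographic grids).

    Geographic grids: (111.32 x cellsize_deg)^2 x cos(latitude at cell
    center); planar grids: the stated cell area everywhere.
    """
    if grid.planar:
        return np.full(grid.shape, grid.cell_size_km ** 2)
    if latitude is not None:
        a = (111.32 * grid.cell_size) ** 2 * math.cos(math.radians(latitude))
        return np.full(grid.shape, a)
    lats = grid.y_origin - (np.arange(grid.n_rows) + 0.5) * grid.cell_size
    per_row = (111.32 * grid.cell_size) ** 2 * np.cos(np.radians(lats))
    return np.repeat(per_row[:, None], grid.n_cols, axis=1)


@dataclass
class GapReport:
    """Per-class protected/unprotected area accounting.

    Areas in km^2; percentages are 100 x protected / total, rounded half-up
    to two decimals. Exactly protected + gap = total per class before
    rounding.
    """

    table: pd.DataFrame
    note: str = "percentages rounded half-up to 2 decimals"

    def row(self, class_name: str) -> pd.Series:
        return self.table.set_index("class").loc[class_name]


def _gap_rows(entries: list[tuple[str, float, float]]) -> GapReport:
    rows = []
    for name, total, protected in entries:
        gap = total - protected
        pct = 100.0 * protected / total if total > 0 else float("nan")
        rows.append(
            {
                "class": name,
                "total_km2": round_half_up(total),
                "protected_km2": round_half_up(protected),
                "protected_pct": round_half_up(pct) if np.isfinite(pct) else np.nan,
                "gap_km2": round_half_up(gap),
            }
        )
    totals = {
        "class": "all",
        "total_km2": round_half_up(sum(e[1] for e in entries)),
        "protected_km2": round_half_up(sum(e[2] for e in entries)),
        "protected_pct": round_half_up(
            100.0 * sum(e[2] for e in entries) / sum(e[1] for e in entries)
        )
        if sum(e[1] for e in entries) > 0
        else np.nan,
        "gap_km2": round_half_up(sum(e[1] - e[2] for e in entries)),
    }
    rows.append(totals)
    return GapReport(table=pd.DataFrame(rows))


def gap_analysis(
    class_raster: np.ndarray,
    classes: HotspotClasses,
    pa: PAMask,
    cell_areas: np.ndarray,
) -> GapReport:
    """Overlay hotspot classes with protected areas and tabulate areas."""
    class_raster = np.asarray(class_raster)
    if class_raster.shape != pa.mask.shape or class_raster.shape != np.asarray(cell_areas).shape:
        raise ValueError("class raster, PA mask and cell areas must share one grid")
    entries = []
    for ci, name in enumerate(classes.names):
        sel = class_raster == ci
        total = float(np.sum(cell_areas[sel]))
        protected = float(np.sum(cell_areas[sel & pa.mask]))
        entries.append((name, total, protected))
    return _gap_rows(entries)


def gap_analysis_table(pairs: dict[str, tuple[float, float]]) -> GapReport:
    """Worked-example mode: per-class (total, protected) areas given directly."""
    for name, (total, protected) in pairs.items():
        if protected > total:
            raise ValueError(f"class {name!r}: protected area exceeds total")
    return _gap_rows([(n, t, p) for n, (t, p) in pairs.items()])


def composition_summary(traits: pd.DataFrame, denominator: int,
                        columns: list[str] | None = None) -> pd.DataFrame:
    """Counts and percentages of species per trait group.

    One output row per (trait column, level): count of species carrying the
    level and 100 x count / denominator rounded half-up to two decimals.
    """
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    if traits.empty:
        return pd.DataFrame(columns=["group", "level", "count", "percent"])
    if columns is None:
        columns = [c for c in traits.columns if c != "species"]
    rows = []
    for col in columns:
        for level, count in traits[col].value_counts().items():
            rows.append(
                {
                    "group": col,
                    "level": level,
                    "count": int(count),
                    "percent": round_half_up(100.0 * count / denominator),
                }
            )
    return pd.DataFrame(rows)
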