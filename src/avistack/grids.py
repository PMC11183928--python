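"""Raster grid containers and plain-text raster I/O.

The whole pipeline operates on a single aligned grid: a stack of named
environmental layers (continuous climate-like surfaces, elevation, and one
categorical land-cover layer) plus boolean masks (nodata, protected areas).
Rasters are written as ESRI ASCII grids, a plain-text format every GIS reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "EnvStack", "PAMask", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Geotransform of a north-up grid.

    ``x_origin``/``y_origin`` locate the north-west corner. ``cell_size`` is in
    decimal degrees for geographic grids; planar grids set ``planar=True`` and
    carry an explicit ``cell_size_km``.
    """

    n_rows: int
    n_cols: int
    x_origin: float = 116.3
    y_origin: float = 35.33
    cell_size: float = 1.0 / 120.0  # 30 arc-seconds
    planar: bool = False
    cell_size_km: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Longitude and latitude (or planar x/y) of every cell center."""
        cols = self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size
        rows = self.y_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size
        lon, lat = np.meshgrid(cols, rows)
        return lon, lat

    def point_to_cell(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the half-open cell containing each point.

        Cells are anchored at the north-west corner: a point on a cell's
        west/north edge belongs to that cell.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - lat) / self.cell_size).astype(int)
        return row, col

    def contains(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        row, col = self.point_to_cell(lon, lat)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


@dataclass
class EnvStack:
    """Aligned multi-layer raster stack.

    ``layers`` maps name -> 2-D float array; ``categorical`` maps the names of
    categorical layers to their legend (sorted list of integer class codes).
    ``nodata`` is True where cells carry no data in any layer.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray]
    categorical: dict[str, list[int]] = field(default_factory=dict)
    nodata: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.nodata is None:
            self.nodata = np.zeros(self.grid.shape, dtype=bool)
        self.nodata = np.asarray(self.nodata, dtype=bool)
        if self.nodata.shape != self.grid.shape:
            raise ValueError("nodata mask shape does not match grid")
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}")
            if not np.all(np.isfinite(arr[~self.nodata])):
                raise ValueError(f"layer {name!r} has non-finite values outside the nodata mask")
            self.layers[name] = arr
        for name, legend in self.categorical.items():
            if name not in self.layers:
                raise ValueError(f"categorical layer {name!r} not in stack")
            codes = np.unique(self.layers[name][~self.nodata])
            unknown = set(codes.astype(int)) - set(legend)
            if unknown:
                raise ValueError(f"layer {name!r} contains codes {sorted(unknown)} not in legend")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def continuous_names(self) -> list[str]:
        return [n for n in self.layers if n not in self.categorical]

    def valid_mask(self) -> np.ndarray:
        return ~self.nodata

    def values_at(self, rows: np.ndarray, cols: np.ndarray) -> dict[str, np.ndarray]:
        return {name: arr[rows, cols] for name, arr in self.layers.items()}

    def flat_values(self) -> dict[str, np.ndarray]:
        """Per-layer 1-D arrays over valid cells, in row-major order."""
        ok = self.valid_mask()
        return {name: arr[ok] for name, arr in self.layers.items()}

    def write_dir(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, arr in self.layers.items():
            p = out_dir / f"{name}.asc"
            write_ascii_grid(p, arr, self.grid, nodata_mask=self.nodata)
            paths[name] = p
        return paths


@dataclass
class PAMask:
    """Boolean protected-area indicator on an :class:`EnvStack` grid."""

    grid: GridSpec
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("PA mask shape does not match grid")

    @property
    def fraction(self) -> float:
        return float(self.mask.mean())


def write_ascii_grid(
    path: str | Path,
    array: np.ndarray,
    grid: GridSpec,
    nodata_mask: np.ndarray | None = None,
    nodata_value: float = -9999.0,
) -> Path:
    """Write a 2-D array as an ESRI ASCII grid (.asc)."""
    path = Path(path)
    array = np.asarray(array, dtype=float)
    if array.shape != grid.shape:
        raise ValueError("array shape does not match grid")
    out = array.copy()
    if nodata_mask is not None:
        out[np.asarray(nodata_mask, dtype=bool)] = nodata_value
    out[~np.isfinite(out)] = nodata_value
    yll = grid.y_origin - grid.n_rows * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_origin!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata_value!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")
    return path


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; returns (array, grid, nodata_mask)."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    arr = np.array(rows, dtype=float)
    if arr.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {arr.shape} does not match header")
    cell = header["cellsize"]
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
    )
    nodata = np.zeros(arr.shape, dtype=bool)
    if "nodata_value" in header:
        nodata = np.isclose(arr, header["nodata_value"])
        arr = arr.copy()
        arr[nodata] = np.nan
    return arr, grid, nodata


def haversine_km(lon1, lat1, lon2, lat2, radius_km: float = 6371.0088):
    """Great-circle distance in kilometres between points in decimal degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def cell_size_km(grid: GridSpec, latitude: float | None = None) -> float:
    """Approximate ground size of one cell edge in km at a latitude."""
    if grid.planar:
        return grid.cell_size_km
    if latitude is None:
        latitude = grid.y_origin - 0.5 * grid.n_rows * grid.cell_size
    return 111.32 * grid.cell_size * math.sqrt(math.cos(math.radians(latitude)))
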