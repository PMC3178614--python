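"""Co-registered environmental grids, layer stacks, and region masks.

Everything downstream (occurrence snapping, model fitting, watershed
extraction) is defined on a single geographic grid: equal-angle cells in
WGS84, addressed by (row, col) with row 0 at the northern edge.  Cell
membership is half-open, ``[west, east) x (south, north]``, so every point
maps to exactly one cell and a point sitting on an interior boundary joins
the cell whose west/north edge it touches.

Rasters are read and written as ESRI ASCII grids (a plain-text header of
``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value`` followed by rows
of numbers, north to south).  Region masks can be rasterized from GeoJSON
polygons by testing cell centers.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import shape as _geojson_shape

__all__ = [
    "GridSpec",
    "Layer",
    "LayerStack",
    "RegionMask",
    "build_grid",
    "assemble_layer_stack",
    "read_ascii_grid",
    "write_ascii_grid",
    "AlignmentError",
]

#: 30 arc-seconds in decimal degrees, the analysis resolution.
ARCSEC30 = 1.0 / 120.0


class AlignmentError(ValueError):
    """Raised when a raster does not share the analysis grid."""


@dataclass(frozen=True)
class GridSpec:
    """Equal-angle analysis grid in geographic (WGS84) coordinates.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; row 0 is the northernmost row.
    cell_size
        Cell edge length in decimal degrees (30 arc-seconds = 1/120).
    origin_lon, origin_lat
        Longitude/latitude of the grid's northwest corner.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_lon: float
    origin_lat: float
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must contain at least one cell")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def west(self) -> float:
        return self.origin_lon

    @property
    def north(self) -> float:
        return self.origin_lat

    @property
    def east(self) -> float:
        return self.origin_lon + self.n_cols * self.cell_size

    @property
    def south(self) -> float:
        return self.origin_lat - self.n_rows * self.cell_size

    def rowcol_of(self, lon, lat):
        """Map coordinates to (row, col) under the half-open convention.

        Returns integer arrays; entries are -1 where the point falls
        outside the grid.  A point on an interior boundary is assigned to
        the cell whose west/north edge it touches.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        tc = (lon - self.origin_lon) / self.cell_size
        tr = (self.origin_lat - lat) / self.cell_size
        # snap float-representation fuzz so exact boundaries floor correctly
        tc = np.where(np.abs(tc - np.round(tc)) < 1e-9, np.round(tc), tc)
        tr = np.where(np.abs(tr - np.round(tr)) < 1e-9, np.round(tr), tr)
        col = np.floor(tc).astype(np.int64)
        row = np.floor(tr).astype(np.int64)
        # (south, north]: the exact north edge of the grid belongs to row 0.
        row = np.where(lat == self.origin_lat, 0, row)
        inside = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        row = np.where(inside, row, -1)
        col = np.where(inside, col, -1)
        if row.ndim == 0:
            return int(row), int(col)
        return row, col

    def cell_id(self, row, col):
        """Flatten (row, col) to a scalar cell index (row-major)."""
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def rowcol_from_id(self, cell_id):
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def cell_center(self, row, col):
        """Longitude/latitude of a cell's center."""
        lon = self.origin_lon + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.origin_lat - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def center_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense (n_rows, n_cols) arrays of cell-center lon and lat."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        lon = self.origin_lon + (cols + 0.5) * self.cell_size
        lat = self.origin_lat - (rows + 0.5) * self.cell_size
        return np.broadcast_to(lon, self.shape).copy(), np.broadcast_to(
            lat[:, None], self.shape
        ).copy()


def build_grid(bounds: Sequence[float], cell_size_deg: float) -> GridSpec:
    """Construct a grid covering ``bounds = (west, south, east, north)``.

    The number of rows/columns is the ceiling of extent / cell size, so the
    grid always covers the requested box (it may overhang east/south when
    the cell size does not divide the extent).
    """
    west, south, east, north = map(float, bounds)
    if not (east > west and north > south):
        raise ValueError("bounds must be a non-degenerate (west, south, east, north) box")
    if not cell_size_deg > 0:
        raise ValueError("cell size must be positive")
    # tolerate float fuzz so 1.0 / 0.25 gives exactly 4 columns
    n_cols = int(math.ceil((east - west) / cell_size_deg - 1e-9))
    n_rows = int(math.ceil((north - south) / cell_size_deg - 1e-9))
    return GridSpec(n_rows=n_rows, n_cols=n_cols, cell_size=cell_size_deg,
                    origin_lon=west, origin_lat=north)


@dataclass
class Layer:
    """One environmental variable on the analysis grid.

    ``values`` is a float array with NaN marking nodata.  Categorical
    layers store small non-negative integer category codes (as floats) and
    declare the admissible codes in ``categories``.
    """

    name: str
    kind: str  # "continuous" | "categorical"
    values: np.ndarray
    categories: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"layer {self.name!r}: values must be 2-D")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"layer {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            present = np.unique(self.values[np.isfinite(self.values)]).astype(int)
            if self.categories is None:
                self.categories = tuple(int(c) for c in present)
            else:
                extra = set(present) - set(self.categories)
                if extra:
                    raise ValueError(
                        f"layer {self.name!r}: undeclared category codes {sorted(extra)}"
                    )

    @property
    def mask(self) -> np.ndarray:
        """Boolean data-present mask."""
        return np.isfinite(self.values)

    def masked(self, keep: np.ndarray) -> "Layer":
        vals = np.where(keep, self.values, np.nan)
        return Layer(self.name, self.kind, vals, self.categories)


@dataclass
class LayerStack:
    """Ordered co-registered layers plus the joint validity mask."""

    grid: GridSpec
    layers: list[Layer]
    set_id: str | None = None

    def __post_init__(self) -> None:
        for lyr in self.layers:
            if lyr.values.shape != self.grid.shape:
                raise AlignmentError(
                    f"layer {lyr.name!r} shape {lyr.values.shape} does not match "
                    f"grid shape {self.grid.shape}"
                )

    @property
    def names(self) -> list[str]:
        return [lyr.name for lyr in self.layers]

    def __getitem__(self, name: str) -> Layer:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(name)

    @property
    def validity_mask(self) -> np.ndarray:
        """Cells where every layer has data (intersection of layer masks)."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for lyr in self.layers:
            mask &= lyr.mask
        return mask

    def subset(self, names: Sequence[str]) -> "LayerStack":
        missing = [n for n in names if n not in self.names]
        if missing:
            raise KeyError(f"unknown layer name(s) in variable set: {missing}")
        return LayerStack(self.grid, [self[n] for n in names], set_id=self.set_id)

    def clip(self, mask: "RegionMask") -> "LayerStack":
        """Set cells outside ``mask`` to nodata in every layer."""
        if mask.values.shape != self.grid.shape:
            raise AlignmentError("region mask shape does not match grid")
        return LayerStack(
            self.grid, [lyr.masked(mask.values) for lyr in self.layers], set_id=self.set_id
        )

    def manifest(self) -> dict:
        return {
            "set_id": self.set_id,
            "grid": {
                "n_rows": self.grid.n_rows,
                "n_cols": self.grid.n_cols,
                "cell_size": self.grid.cell_size,
                "origin_lon": self.grid.origin_lon,
                "origin_lat": self.grid.origin_lat,
            },
            "layers": [
                {"name": lyr.name, "kind": lyr.kind,
                 "categories": list(lyr.categories) if lyr.categories else None}
                for lyr in self.layers
            ],
        }


@dataclass
class RegionMask:
    """Grid-aligned boolean mask (watershed, basin, political extent)."""

    grid: GridSpec
    values: np.ndarray
    name: str = "region"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise AlignmentError(
                f"mask {self.name!r} shape {self.values.shape} != grid {self.grid.shape}"
            )

    @property
    def n_cells(self) -> int:
        return int(self.values.sum())

    def cell_ids(self) -> np.ndarray:
        rows, cols = np.nonzero(self.values)
        return np.asarray(self.grid.cell_id(rows, cols))

    @classmethod
    def from_geojson(cls, geojson: Mapping | str | Path, grid: GridSpec,
                     name: str = "region") -> "RegionMask":
        """Rasterize a GeoJSON polygon: a cell is inside iff its center is.

        Accepts a Feature, FeatureCollection, or bare geometry, given as a
        mapping or a path to a .geojson file.
        """
        if isinstance(geojson, (str, Path)):
            geojson = json.loads(Path(geojson).read_text())
        geom = _extract_geometry(geojson)
        lon, lat = grid.center_arrays()
        inside = shapely.intersects_xy(geom, lon.ravel(), lat.ravel())
        return cls(grid, inside.reshape(grid.shape), name=name)


def _extract_geometry(obj: Mapping):
    t = obj.get("type")
    if t == "FeatureCollection":
        geoms = [_geojson_shape(f["geometry"]) for f in obj["features"]]
        return shapely.union_all(geoms)
    if t == "Feature":
        return _geojson_shape(obj["geometry"])
    return _geojson_shape(obj)


def assemble_layer_stack(
    rasters: Mapping[str, Layer],
    grid: GridSpec,
    variable_set: Sequence[str] | None = None,
    extent_mask: RegionMask | None = None,
    set_id: str | None = None,
) -> LayerStack:
    """Assemble a named subset of aligned rasters into a LayerStack.

    ``variable_set`` selects layers by name in the declared order (None
    keeps all, in mapping order).  Cells outside ``extent_mask`` become
    nodata.  All rasters must already be on ``grid``; a shape mismatch
    raises :class:`AlignmentError`.
    """
    names = list(variable_set) if variable_set is not None else list(rasters)
    unknown = [n for n in names if n not in rasters]
    if unknown:
        raise KeyError(f"unknown layer name(s) in variable set: {unknown}")
    stack = LayerStack(grid, [rasters[n] for n in names], set_id=set_id)
    if extent_mask is not None:
        stack = stack.clip(extent_mask)
    if not stack.validity_mask.any():
        warnings.warn("assembled stack has no valid cells", stacklevel=2)
    return stack


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

def write_ascii_grid(path: str | Path, values: np.ndarray, grid: GridSpec,
                     nodata: float = -9999.0) -> None:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise AlignmentError("values shape does not match grid")
    out = np.where(np.isfinite(values), values, nodata)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.west!r}\n"
        f"yllcorner {grid.south!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; nodata becomes NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing {key} in ASCII grid header")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {data.shape} != header ({n_rows}, {n_cols})")
    cell = header["cellsize"]
    xll = header.get("xllcorner", 0.0)
    yll = header.get("yllcorner", 0.0)
    grid = GridSpec(n_rows=n_rows, n_cols=n_cols, cell_size=cell,
                    origin_lon=xll, origin_lat=yll + n_rows * cell)
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return data, grid


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
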