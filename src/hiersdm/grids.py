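"""Regular geographic lattices and the raster layers that live on them.

Every map in the pipeline — predictor, suitability, richness, zone — is a
:class:`RasterLayer` on a shared :class:`GridSpec`.  The grid is a plain
lon/lat lattice (row 0 at the southern edge) with half-open, lower-inclusive
cells: a point on a cell's southern or western edge belongs to that cell, a
point on the northern or eastern edge belongs to the neighbour.

On-disk format is a readable ASCII grid (header line
``n_rows n_cols min_lon min_lat cell_size nodata`` followed by ``n_rows``
rows of values, southern row first).  Rotated or projected grids are out of
scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "GridSpec",
    "RasterLayer",
    "RasterStack",
    "OUTSIDE",
    "point_to_cell",
    "points_to_cells",
    "read_raster",
    "write_raster",
    "aggregate_to_grid",
]

#: Sentinel returned by :func:`point_to_cell` for points off the lattice.
OUTSIDE = (-1, -1)

_DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat lattice.

    Cell ``(r, c)`` covers the half-open box
    ``[min_lon + c*s, min_lon + (c+1)*s) x [min_lat + r*s, min_lat + (r+1)*s)``
    with ``s = cell_size``; row 0 is the southernmost row.
    """

    min_lon: float
    min_lat: float
    cell_size: float = 0.25
    n_rows: int = 1
    n_cols: int = 1
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if not (self.cell_size > 0):
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def max_lon(self) -> float:
        return self.min_lon + self.n_cols * self.cell_size

    @property
    def max_lat(self) -> float:
        return self.min_lat + self.n_rows * self.cell_size

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the centre of cell (row, col)."""
        s = self.cell_size
        return (self.min_lon + (col + 0.5) * s, self.min_lat + (row + 0.5) * s)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (lon, lat), each of grid shape, of all cell centres."""
        s = self.cell_size
        lon = self.min_lon + (np.arange(self.n_cols) + 0.5) * s
        lat = self.min_lat + (np.arange(self.n_rows) + 0.5) * s
        return np.meshgrid(lon, lat)

    def contains_grid(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        """True if `other` is an aligned sub-extent of this grid."""
        if abs(other.cell_size - self.cell_size) > tol:
            return False
        dlon = (other.min_lon - self.min_lon) / self.cell_size
        dlat = (other.min_lat - self.min_lat) / self.cell_size
        if abs(dlon - round(dlon)) > tol or abs(dlat - round(dlat)) > tol:
            return False
        r0, c0 = int(round(dlat)), int(round(dlon))
        return (
            r0 >= 0
            and c0 >= 0
            and r0 + other.n_rows <= self.n_rows
            and c0 + other.n_cols <= self.n_cols
        )

    def offset_of(self, other: "GridSpec") -> tuple[int, int]:
        """(row, col) offset of `other`'s origin within this grid."""
        if not self.contains_grid(other):
            raise ValueError("grid is not an aligned sub-extent")
        return (
            int(round((other.min_lat - self.min_lat) / self.cell_size)),
            int(round((other.min_lon - self.min_lon) / self.cell_size)),
        )


def point_to_cell(grid: GridSpec, lon: float, lat: float) -> tuple[int, int]:
    """Map a point to its (row, col) cell, or :data:`OUTSIDE`.

    Assignment is half-open and lower-inclusive: a point on a cell's lower
    (southern/western) edge belongs to that cell.
    """
    if not (math.isfinite(lon) and math.isfinite(lat)):
        raise ValueError(f"non-finite coordinates ({lon}, {lat})")
    col = math.floor((lon - grid.min_lon) / grid.cell_size)
    row = math.floor((lat - grid.min_lat) / grid.cell_size)
    if 0 <= row < grid.n_rows and 0 <= col < grid.n_cols:
        return (row, col)
    return OUTSIDE


def points_to_cells(
    grid: GridSpec, lon: np.ndarray, lat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`point_to_cell`; out-of-extent points get (-1, -1)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if not (np.isfinite(lon).all() and np.isfinite(lat).all()):
        raise ValueError("non-finite coordinates")
    col = np.floor((lon - grid.min_lon) / grid.cell_size).astype(int)
    row = np.floor((lat - grid.min_lat) / grid.cell_size).astype(int)
    bad = (row < 0) | (row >= grid.n_rows) | (col < 0) | (col >= grid.n_cols)
    row[bad] = -1
    col[bad] = -1
    return row, col


@dataclass
class RasterLayer:
    """Per-cell real values plus a nodata mask on a :class:`GridSpec`.

    ``mask`` is True where the cell holds no data; ``values`` is meaningful
    exactly where ``mask`` is False.
    """

    grid: GridSpec
    name: str
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid shape")

    @property
    def valid(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return ~self.mask

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterLayer":
        """New layer on the same grid/mask with different values."""
        return RasterLayer(self.grid, name or self.name, values, self.mask.copy())

    def extract(self, sub: GridSpec, name: str | None = None) -> "RasterLayer":
        """Clip to an aligned sub-extent grid."""
        r0, c0 = self.grid.offset_of(sub)
        return RasterLayer(
            sub,
            name or self.name,
            self.values[r0 : r0 + sub.n_rows, c0 : c0 + sub.n_cols].copy(),
            self.mask[r0 : r0 + sub.n_rows, c0 : c0 + sub.n_cols].copy(),
        )


@dataclass
class RasterStack:
    """Ordered, uniquely named layers sharing one grid."""

    grid: GridSpec
    layers: list[RasterLayer] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names: {names}")
        for l in self.layers:
            if l.grid != self.grid:
                raise ValueError(f"layer {l.name!r} is on a different grid")

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self) -> Iterator[RasterLayer]:
        return iter(self.layers)

    def __getitem__(self, name: str) -> RasterLayer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def add(self, layer: RasterLayer) -> None:
        if layer.name in self:
            raise ValueError(f"layer {layer.name!r} already in stack")
        if layer.grid != self.grid:
            raise ValueError("layer grid mismatch")
        self.layers.append(layer)

    def select(self, names: list[str]) -> "RasterStack":
        return RasterStack(self.grid, [self[n] for n in names])

    def extract(self, sub: GridSpec) -> "RasterStack":
        return RasterStack(sub, [l.extract(sub) for l in self.layers])

    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        m = np.ones(self.grid.shape, dtype=bool)
        for l in self.layers:
            m &= l.valid
        return m

    def table(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n_points, n_layers) matrix of layer values at the given cells."""
        return np.column_stack([l.values[rows, cols] for l in self.layers])


def write_raster(layer: RasterLayer, path: str | Path) -> None:
    """Write a layer as an ASCII grid (southern row first)."""
    path = Path(path)
    vals = np.where(layer.mask, _DEFAULT_NODATA, layer.values)
    g = layer.grid
    header = (
        f"{g.n_rows} {g.n_cols} {g.min_lon:.17g} {g.min_lat:.17g} "
        f"{g.cell_size:.17g} {_DEFAULT_NODATA:.17g}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        for r in range(g.n_rows):
            fh.write(" ".join(f"{v:.17g}" for v in vals[r]) + "\n")


def read_raster(path: str | Path, name: str | None = None) -> RasterLayer:
    """Read an ASCII grid written by :func:`write_raster`."""
    path = Path(path)
    with path.open() as fh:
        head = fh.readline().split()
        if len(head) != 6:
            raise ValueError(
                f"{path}: unsupported format (expected 6-field header, got {head})"
            )
        n_rows, n_cols = int(head[0]), int(head[1])
        min_lon, min_lat, cell_size, nodata = map(float, head[2:])
        vals = np.loadtxt(fh, dtype=float, ndmin=2)
    if vals.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: body shape {vals.shape} != header {(n_rows, n_cols)}")
    grid = GridSpec(min_lon, min_lat, cell_size, n_rows, n_cols)
    mask = vals == nodata
    return RasterLayer(grid, name or path.stem, np.where(mask, np.nan, vals), mask)


def write_stack(stack: RasterStack, directory: str | Path) -> None:
    """Write each layer of a stack as ``<directory>/<name>.asc``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for layer in stack:
        write_raster(layer, directory / f"{layer.name}.asc")


def read_stack(directory: str | Path, names: list[str]) -> RasterStack:
    """Read named layers from ``<directory>/<name>.asc``."""
    directory = Path(directory)
    layers = [read_raster(directory / f"{n}.asc", name=n) for n in names]
    return RasterStack(layers[0].grid, layers)


def aggregate_to_grid(fine: RasterLayer, coarse: GridSpec, tol: float = 1e-9) -> RasterLayer:
    """Block-average a fine layer onto a coarser aligned grid.

    Each coarse cell is the unweighted mean of its valid fine contributors;
    it is nodata only when every contributor is nodata.  The coarse cell size
    must be an integer multiple of the fine cell size and origins must align.
    """
    fg = fine.grid
    ratio = coarse.cell_size / fg.cell_size
    k = round(ratio)
    if k < 1 or abs(ratio - k) > tol:
        raise ValueError(
            f"coarse cell size {coarse.cell_size} is not an integer multiple "
            f"of fine cell size {fg.cell_size}"
        )
    if (
        abs(fg.min_lon - coarse.min_lon) > tol
        or abs(fg.min_lat - coarse.min_lat) > tol
        or fg.n_rows != coarse.n_rows * k
        or fg.n_cols != coarse.n_cols * k
    ):
        raise ValueError("fine and coarse grids are misaligned")

    vals = np.where(fine.mask, 0.0, fine.values)
    cnt = (~fine.mask).astype(float)
    # sum over k x k blocks
    vals = vals.reshape(coarse.n_rows, k, coarse.n_cols, k).sum(axis=(1, 3))
    cnt = cnt.reshape(coarse.n_rows, k, coarse.n_cols, k).sum(axis=(1, 3))
    mask = cnt == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(mask, np.nan, vals / np.where(cnt == 0, 1.0, cnt))
    return RasterLayer(coarse, fine.name, mean, mask)
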