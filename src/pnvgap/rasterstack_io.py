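"""Raster containers, text-grid I/O, resampling, rasterization and zonal statistics.

Every layer in the analysis is a single-band raster on a shared rectangular
grid. Grids are strictly co-registered: two layers may be combined only when
their :class:`GridSpec` objects compare equal — there is no silent
reprojection or resampling; callers must call :func:`resample_to_grid`
explicitly. The coordinate convention, used everywhere in the package, is:
row 0 is the northernmost row and cell ``(i, j)`` has its center at
``origin + ((j + 0.5) * cell_size, -(i + 0.5) * cell_size)``.

Rasters are exchanged on disk as ESRI ASCII grids (``.asc``), a plain-text
interchange format readable by every GIS, with a ``.prj`` sidecar holding the
CRS label. Scores are stored as floats, categorical codes as integers, and
nodata cells as the header's sentinel value.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

__all__ = [
    "GridSpec",
    "Raster",
    "LayerStack",
    "GridAlignmentError",
    "RasterIOError",
    "read_raster",
    "write_raster",
    "resample_to_grid",
    "rasterize_polygons",
    "zonal_stat",
    "raster_checksum",
]

DEFAULT_NODATA = -9999.0


class GridAlignmentError(ValueError):
    """Raised when an operation receives rasters that are not co-registered."""


class RasterIOError(IOError):
    """Raised when a raster file is missing, unreadable or lacks georeferencing."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up rectangular analysis grid.

    ``origin`` is the map coordinate of the grid's top-left (north-west)
    corner. ``cell_size`` is in metres; the default 900 m matches the
    resolution at which all analysis layers are harmonised.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 900.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "local"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(f"grid must be at least 1x1, got {self.n_rows}x{self.n_cols}")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, i: np.ndarray | int, j: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of the center of cell(s) ``(i, j)``."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(j) + 0.5) * self.cell_size
        y = y0 - (np.asarray(i) + 0.5) * self.cell_size
        return x, y

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the cells containing map points ``(x, y)``.

        Points outside the grid get out-of-range indices; callers clip or
        filter as appropriate.
        """
        x0, y0 = self.origin
        j = np.floor((np.asarray(x) - x0) / self.cell_size).astype(np.int64)
        i = np.floor((y0 - np.asarray(y)) / self.cell_size).astype(np.int64)
        return i, j

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        x0, y0 = self.origin
        return (x0, y0 - self.n_rows * self.cell_size, x0 + self.n_cols * self.cell_size, y0)


@dataclass
class Raster:
    """A single-band raster: values plus a nodata mask on a :class:`GridSpec`.

    ``mask`` follows the numpy.ma convention: True marks a nodata cell.
    """

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.mask is None:
            self.mask = np.zeros(self.grid.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {self.grid.shape}")
        if self.mask.shape != self.grid.shape:
            raise ValueError(f"mask shape {self.mask.shape} != grid shape {self.grid.shape}")

    @classmethod
    def full(cls, grid: GridSpec, fill: float, dtype=np.float64) -> "Raster":
        return cls(grid, np.full(grid.shape, fill, dtype=dtype))

    @property
    def valid(self) -> np.ndarray:
        """Boolean array, True where the cell carries data."""
        return ~self.mask

    def compressed(self) -> np.ndarray:
        """1-D array of the unmasked values."""
        return self.values[self.valid]

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy(), self.mask.copy())

    def is_coregistered(self, other: "Raster") -> bool:
        return self.grid == other.grid


def _require_coregistered(*rasters: Raster) -> None:
    first = rasters[0].grid
    for r in rasters[1:]:
        if r.grid != first:
            raise GridAlignmentError(
                f"rasters are not co-registered: {first} vs {r.grid}; resample explicitly"
            )


class LayerStack(Mapping[str, Raster]):
    """An ordered, named mapping of co-registered rasters."""

    def __init__(self, layers: Mapping[str, Raster] | Iterable[tuple[str, Raster]]):
        self._layers: dict[str, Raster] = dict(layers)
        if not self._layers:
            raise ValueError("LayerStack requires at least one layer")
        _require_coregistered(*self._layers.values())

    def __getitem__(self, name: str) -> Raster:
        return self._layers[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    @property
    def grid(self) -> GridSpec:
        return next(iter(self._layers.values())).grid

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def as_array(self) -> np.ndarray:
        """Stack of shape (n_layers, n_rows, n_cols)."""
        return np.stack([r.values for r in self._layers.values()])

    def combined_valid(self) -> np.ndarray:
        """Cells valid in every member layer (nodata propagates)."""
        out = np.ones(self.grid.shape, dtype=bool)
        for r in self._layers.values():
            out &= r.valid
        return out


# ---------------------------------------------------------------------------
# I/O — ESRI ASCII grid with .prj sidecar
# ---------------------------------------------------------------------------

def write_raster(raster: Raster, path: str | os.PathLike, nodata: float = DEFAULT_NODATA) -> None:
    """Write a raster as an ESRI ASCII grid plus a ``.prj`` CRS sidecar.

    Integer-valued rasters are written without decimal points so that the
    round trip is value-exact; masked cells are written as the nodata
    sentinel.
    """
    path = os.fspath(path)
    g = raster.grid
    vals = np.array(raster.values, dtype=np.float64)
    if np.any(raster.valid & (vals == nodata)):
        raise RasterIOError(f"data contains the nodata sentinel {nodata}; choose another")
    vals[raster.mask] = nodata
    integral = np.all(vals == np.floor(vals))
    xll, yll = g.origin[0], g.origin[1] - g.n_rows * g.cell_size
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {xll!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    fmt = "%d" if integral else "%.17g"  # 17 significant digits: float64 round-trips exactly
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)
    with open(_prj_path(path), "w", encoding="utf-8") as fh:
        fh.write(raster.grid.crs_id + "\n")


def _prj_path(path: str) -> str:
    stem, _ = os.path.splitext(path)
    return stem + ".prj"


def read_raster(path: str | os.PathLike) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_raster`.

    The grid geometry comes from the file header; the CRS label from the
    ``.prj`` sidecar (``"local"`` when absent). Cells equal to the header's
    nodata sentinel are masked.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise RasterIOError(f"raster file not found: {path}")
    header: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or parts[0][0].isdigit() or parts[0][0] in "+-.":
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(pos)
        try:
            data = np.loadtxt(fh, ndmin=2)
        except ValueError as exc:
            raise RasterIOError(f"unreadable raster body in {path}: {exc}") from None
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required.issubset(header):
        missing = sorted(required - set(header))
        raise RasterIOError(f"missing georeferencing keys {missing} in {path}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (n_rows, n_cols):
        raise RasterIOError(f"body shape {data.shape} disagrees with header ({n_rows}, {n_cols})")
    crs_id = "local"
    if os.path.exists(_prj_path(path)):
        with open(_prj_path(path), "r", encoding="utf-8") as fh:
            crs_id = fh.read().strip() or "local"
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + n_rows * cell)
    grid = GridSpec(n_rows, n_cols, cell, origin, crs_id)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    mask = data == nodata
    return Raster(grid, data, mask)


def raster_checksum(raster: Raster) -> str:
    """SHA-256 over the raster's values and mask, for provenance records."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(raster.values, dtype=np.float64).tobytes())
    h.update(np.ascontiguousarray(raster.mask).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_grid(raster: Raster, target: GridSpec, mode: str = "nearest",
                     categorical: bool = False) -> Raster:
    """Resample a raster onto ``target``.

    ``mode="nearest"`` assigns each target cell the value of the source cell
    containing its center (never invents codes, required for categorical
    layers). ``mode="mean"`` averages the unmasked source cells whose centers
    fall inside each target cell — for aligned integer aggregation factors
    this is exactly the block mean. Requesting ``mean`` with
    ``categorical=True`` is an error.
    """
    if mode not in ("nearest", "mean"):
        raise ValueError(f"unknown resampling mode {mode!r}")
    if mode == "mean" and categorical:
        raise ValueError("mean resampling is invalid for categorical rasters")
    src = raster.grid
    if mode == "nearest":
        jj, ii = np.meshgrid(np.arange(target.n_cols), np.arange(target.n_rows))
        x, y = target.cell_center(ii, jj)
        si, sj = src.index_of(x, y)
        inside = (si >= 0) & (si < src.n_rows) & (sj >= 0) & (sj < src.n_cols)
        si_c, sj_c = np.clip(si, 0, src.n_rows - 1), np.clip(sj, 0, src.n_cols - 1)
        values = raster.values[si_c, sj_c]
        mask = ~inside | raster.mask[si_c, sj_c]
        return Raster(target, np.where(mask, 0, values), mask)
    # mean: scatter source cell centers into target cells
    jj, ii = np.meshgrid(np.arange(src.n_cols), np.arange(src.n_rows))
    x, y = src.cell_center(ii, jj)
    ti, tj = target.index_of(x, y)
    ok = (ti >= 0) & (ti < target.n_rows) & (tj >= 0) & (tj < target.n_cols) & raster.valid
    flat = ti[ok] * target.n_cols + tj[ok]
    n_bins = target.n_rows * target.n_cols
    counts = np.bincount(flat, minlength=n_bins)
    sums = np.bincount(flat, weights=raster.values[ok].astype(np.float64), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    mask = (counts == 0).reshape(target.shape)
    return Raster(target, np.where(mask.ravel(), 0.0, means).reshape(target.shape), mask)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize_polygons(polys: Sequence[tuple[BaseGeometry, int]], grid: GridSpec,
                       combine: str = "last") -> Raster:
    """Burn polygons into a categorical raster by cell-center containment.

    Each cell whose center lies strictly inside a polygon takes that
    polygon's integer attribute; cells covered by no polygon are masked.
    Where polygons overlap, ``combine`` resolves the conflict: ``"last"``
    (paint order), ``"min"`` or ``"max"`` of the attribute values.
    """
    if combine not in ("last", "min", "max"):
        raise ValueError(f"unknown combine rule {combine!r}")
    out = np.zeros(grid.shape, dtype=np.int64)
    covered = np.zeros(grid.shape, dtype=bool)
    for k, (geom, attr) in enumerate(polys):
        if geom is None or geom.is_empty:
            continue
        if not geom.is_valid:
            raise ValueError(f"invalid geometry for polygon #{k} (attribute {attr})")
        xmin, ymin, xmax, ymax = geom.bounds
        i_hi, j_lo = grid.index_of(np.asarray(xmin), np.asarray(ymin))
        i_lo, j_hi = grid.index_of(np.asarray(xmax), np.asarray(ymax))
        # note: y decreases with row index, so ymax -> smallest row
        r0 = max(int(i_lo), 0)
        r1 = min(int(i_hi) + 1, grid.n_rows)
        c0 = max(int(j_lo), 0)
        c1 = min(int(j_hi) + 1, grid.n_cols)
        if r0 >= r1 or c0 >= c1:
            continue
        jj, ii = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        x, y = grid.cell_center(ii, jj)
        shapely.prepare(geom)
        hit = shapely.contains_xy(geom, x.ravel(), y.ravel()).reshape(ii.shape)
        sub_cov = covered[r0:r1, c0:c1]
        sub_out = out[r0:r1, c0:c1]
        if combine == "last":
            sub_out[hit] = attr
        elif combine == "min":
            sub_out[hit & sub_cov] = np.minimum(sub_out[hit & sub_cov], attr)
            sub_out[hit & ~sub_cov] = attr
        else:
            sub_out[hit & sub_cov] = np.maximum(sub_out[hit & sub_cov], attr)
            sub_out[hit & ~sub_cov] = attr
        sub_cov |= hit
    return Raster(grid, out, ~covered)


# ---------------------------------------------------------------------------
# Zonal statistics
# ---------------------------------------------------------------------------

_STATS = ("mean", "median", "mad", "percent_where")


def zonal_stat(values: Raster, zones: Raster, stat: str = "mean",
               predicate: Callable[[np.ndarray], np.ndarray] | None = None) -> pd.DataFrame:
    """Per-zone statistic of ``values`` over the integer-coded ``zones`` raster.

    Supported statistics: ``mean``, ``median``, ``mad`` (median absolute
    deviation from the median, unscaled) and ``percent_where`` (percentage of
    the zone's unmasked cells where ``predicate(values)`` holds). Cells
    masked in either raster are excluded; zones with no remaining cells are
    reported with a NaN value. Returns a DataFrame with columns
    ``zone``, ``value`` and ``n_cells``.
    """
    if stat not in _STATS:
        raise ValueError(f"unknown statistic {stat!r}; choose from {_STATS}")
    if stat == "percent_where" and predicate is None:
        raise ValueError("percent_where requires a predicate")
    _require_coregistered(values, zones)
    ok = values.valid & zones.valid
    zcodes = np.unique(zones.values[zones.valid]).astype(np.int64)
    rows = []
    for z in zcodes:
        sel = ok & (zones.values == z)
        v = values.values[sel].astype(np.float64)
        n = v.size
        if n == 0:
            rows.append((int(z), np.nan, 0))
            continue
        if stat == "mean":
            val = float(np.mean(v))
        elif stat == "median":
            val = float(np.median(v))
        elif stat == "mad":
            val = float(np.median(np.abs(v - np.median(v))))
        else:
            val = 100.0 * float(np.count_nonzero(predicate(v))) / n
        rows.append((int(z), val, n))
    return pd.DataFrame(rows, columns=["zone", "value", "n_cells"])
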