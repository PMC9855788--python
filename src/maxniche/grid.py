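"""Raster data model and I/O.

A :class:`Grid` is a single 2-D layer of cell values on a regular
longitude/latitude lattice (row 0 at the northern edge) with a nodata
sentinel; a :class:`GridStack` is an ordered, aligned set of named layers
(e.g. the bioclimatic codes ``Bio1`` ... ``Bio19``).  Two on-disk formats are
supported: single-band GeoTIFF (via :mod:`tifffile` with the standard
GeoTIFF georeferencing tags) and the ESRI ASCII grid.

A lon/lat point maps to the cell containing it under half-open intervals
``[west, east)`` in longitude and ``(south, north]`` in latitude, so every
point belongs to exactly one cell.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = [
    "Grid",
    "GridStack",
    "GridFormatError",
    "AlignmentError",
    "read_grid",
    "write_grid",
    "stack_layers",
    "valid_mask",
]

DEFAULT_NODATA = -9999.0

# GeoTIFF tag ids
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113


class GridFormatError(ValueError):
    """Raised when a raster file cannot be parsed as the named format."""


class AlignmentError(ValueError):
    """Raised when layers of a stack disagree in shape or georeferencing."""


@dataclass
class Grid:
    """Single raster layer with affine georeferencing and a nodata mask.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values, row 0 at the northern edge.
    transform : tuple (west, north, cell_size_deg)
        Longitude of the western edge, latitude of the northern edge, and
        the (square) cell size in decimal degrees.
    nodata : float
        Sentinel marking invalid cells.  NaN cells are also invalid.
    crs_tag : str
        Coordinate reference tag; only geographic WGS84 is supported.
    """

    values: np.ndarray
    transform: tuple[float, float, float]
    nodata: float = DEFAULT_NODATA
    crs_tag: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"grid values must be 2-D, got {self.values.ndim}-D")
        if self.transform[2] <= 0:
            raise ValueError("cell_size_deg must be positive")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def west(self) -> float:
        return self.transform[0]

    @property
    def north(self) -> float:
        return self.transform[1]

    @property
    def cell_size(self) -> float:
        return self.transform[2]

    @property
    def south(self) -> float:
        return self.north - self.shape[0] * self.cell_size

    @property
    def east(self) -> float:
        return self.west + self.shape[1] * self.cell_size

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a valid value."""
        with np.errstate(invalid="ignore"):
            return ~(np.isnan(self.values) | (self.values == self.nodata))

    def valid_values(self) -> np.ndarray:
        """1-D array of the valid cell values."""
        return self.values[self.mask]

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Cell (row, col) containing the point, or None if outside.

        Uses [west, east) x (south, north] so edge points are unambiguous.
        """
        west, north, cs = self.transform
        col = math.floor((lon - west) / cs)
        # (south, north]: lat == north -> row 0; a boundary latitude falls in
        # the row below it, which floor already delivers
        row = math.floor((north - lat) / cs)
        nrows, ncols = self.shape
        if 0 <= row < nrows and 0 <= col < ncols:
            return row, col
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        west, north, cs = self.transform
        return west + (col + 0.5) * cs, north - (row + 0.5) * cs

    def aligned_with(self, other: "Grid", tol: float = 1e-9) -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= tol for a, b in zip(self.transform, other.transform)
        )

    def with_values(self, values: np.ndarray) -> "Grid":
        """New grid sharing this grid's georeferencing."""
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class GridStack:
    """Ordered map from layer code (e.g. ``"Bio1"``) to aligned :class:`Grid`."""

    layers: dict[str, Grid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = list(self.layers)
        if not codes:
            return
        ref = self.layers[codes[0]]
        for code in codes[1:]:
            g = self.layers[code]
            if not ref.aligned_with(g):
                raise AlignmentError(
                    f"layer {code!r} (shape {g.shape}, transform {g.transform}) is not "
                    f"aligned with layer {codes[0]!r} (shape {ref.shape}, "
                    f"transform {ref.transform})"
                )

    @property
    def codes(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def transform(self) -> tuple[float, float, float]:
        return next(iter(self.layers.values())).transform

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, code: str) -> Grid:
        return self.layers[code]

    def __contains__(self, code: str) -> bool:
        return code in self.layers

    def subset(self, codes: list[str]) -> "GridStack":
        missing = [c for c in codes if c not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return GridStack({c: self.layers[c] for c in codes})

    def values_at(self, cells: np.ndarray, codes: list[str] | None = None) -> np.ndarray:
        """Matrix (n_cells, n_layers) of layer values at (row, col) cells."""
        codes = codes if codes is not None else self.codes
        cells = np.asarray(cells)
        rows, cols = cells[:, 0], cells[:, 1]
        return np.column_stack([self.layers[c].values[rows, cols] for c in codes])


def stack_layers(grids: list[tuple[str, Grid]]) -> GridStack:
    """Assemble named layers into an aligned stack.

    Raises :class:`AlignmentError` on shape/transform mismatch and
    ``ValueError`` on duplicate layer codes.
    """
    if not grids:
        raise ValueError("stack requires at least one layer")
    layers: dict[str, Grid] = {}
    for code, grid in grids:
        if code in layers:
            raise ValueError(f"duplicate layer code {code!r}")
        layers[code] = grid
    return GridStack(layers)


def valid_mask(stack: GridStack) -> Grid:
    """Boolean grid, True exactly where every layer holds valid data."""
    if len(stack) == 0:
        raise ValueError("empty stack has no mask")
    grids = list(stack.layers.values())
    m = grids[0].mask.copy()
    for g in grids[1:]:
        m &= g.mask
    ref = grids[0]
    return Grid(m.astype(float), ref.transform, nodata=-1.0, crs_tag=ref.crs_tag)


# -- ESRI ASCII ------------------------------------------------------------

_ASCII_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}


def _read_esri_ascii(path: str) -> Grid:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _ASCII_HEADER_KEYS | {"nodata_value"}:
                if len(parts) != 2:
                    raise GridFormatError(f"malformed header line {line.strip()!r}")
                try:
                    header[key] = float(parts[1])
                except ValueError as exc:
                    raise GridFormatError(f"non-numeric header field {key!r}") from exc
            else:
                data_lines.append(line)
    missing = _ASCII_HEADER_KEYS - set(header)
    if missing:
        raise GridFormatError(f"missing ESRI ASCII header field(s): {sorted(missing)}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    try:
        values = np.loadtxt(data_lines, dtype=float, ndmin=2)
    except ValueError as exc:
        raise GridFormatError(f"unparseable grid body in {path}: {exc}") from exc
    values = values.reshape(-1)
    if values.size != nrows * ncols:
        raise GridFormatError(
            f"grid body has {values.size} values, header declares {nrows}x{ncols}"
        )
    values = values.reshape(nrows, ncols)
    cs = header["cellsize"]
    if cs <= 0:
        raise GridFormatError("cellsize must be positive")
    west = header["xllcorner"]
    north = header["yllcorner"] + nrows * cs
    return Grid(values, (west, north, cs), nodata=nodata)


def _write_esri_ascii(grid: Grid, path: str) -> None:
    nrows, ncols = grid.shape
    vals = np.where(grid.mask, grid.values, grid.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.west:.10g}\n")
        fh.write(f"yllcorner {grid.south:.10g}\n")
        fh.write(f"cellsize {grid.cell_size:.10g}\n")
        fh.write(f"NODATA_value {grid.nodata:.10g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


# -- GeoTIFF ---------------------------------------------------------------

def _read_geotiff(path: str) -> Grid:
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray()
            tags = page.tags
            if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
                raise GridFormatError(
                    f"{path}: missing GeoTIFF georeferencing tags "
                    "(ModelPixelScale/ModelTiepoint)"
                )
            sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
            tie = tags[_TAG_TIEPOINT].value
            nodata = DEFAULT_NODATA
            if _TAG_GDAL_NODATA in tags:
                nodata = float(tags[_TAG_GDAL_NODATA].value)
            crs_tag = "EPSG:4326"
            if _TAG_GEO_KEYS in tags:
                keys = tags[_TAG_GEO_KEYS].value
                # entries of 4 shorts: (key id, location, count, value)
                for i in range(4, len(keys), 4):
                    if keys[i] == 2048:
                        crs_tag = f"EPSG:{keys[i + 3]}"
    except tifffile.TiffFileError as exc:
        raise GridFormatError(f"{path}: not a readable TIFF: {exc}") from exc
    if abs(sx - sy) > 1e-9 * max(sx, sy):
        raise GridFormatError(f"{path}: non-square pixels ({sx} x {sy}) unsupported")
    if values.ndim != 2:
        raise GridFormatError(f"{path}: expected single-band raster, got shape {values.shape}")
    # tiepoint maps raster point (i, j) to model point (x, y): upper-left corner
    i, j, _, x, y, _ = tie[:6]
    west = x - i * sx
    north = y + j * sy
    return Grid(values.astype(float), (west, north, float(sx)), nodata=nodata, crs_tag=crs_tag)


def _write_geotiff(grid: Grid, path: str) -> None:
    cs = grid.cell_size
    epsg = 4326
    if grid.crs_tag.upper().startswith("EPSG:"):
        epsg = int(grid.crs_tag.split(":")[1])
    vals = np.where(grid.mask, grid.values, grid.nodata).astype(np.float32)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.west, grid.north, 0.0)),
        (_TAG_GEO_KEYS, "H", 16,
         (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, epsg)),
        (_TAG_GDAL_NODATA, "s", 0, f"{grid.nodata:.10g}"),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def read_grid(path: str, format: str | None = None) -> Grid:
    """Read a raster layer from GeoTIFF or ESRI ASCII.

    ``format`` is ``"geotiff"`` or ``"esri_ascii"``; if omitted it is
    inferred from the file extension (.tif/.tiff vs .asc/.txt).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    if fmt == "esri_ascii":
        return _read_esri_ascii(path)
    raise ValueError(f"unknown raster format {fmt!r}")


def write_grid(grid: Grid, path: str, format: str | None = None) -> None:
    """Write a raster layer; the file is re-readable by :func:`read_grid`."""
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    fmt = format or _infer_format(path)
    if fmt == "geotiff":
        _write_geotiff(grid, path)
    elif fmt == "esri_ascii":
        _write_esri_ascii(grid, path)
    else:
        raise ValueError(f"unknown raster format {fmt!r}")


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in {".tif", ".tiff"}:
        return "geotiff"
    if ext in {".asc", ".txt", ".grd"}:
        return "esri_ascii"
    raise ValueError(f"cannot infer raster format from extension {ext!r}")
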