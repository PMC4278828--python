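"""Raster data model, georeferencing, I/O and resampling.

A :class:`Grid` is one georeferenced 2D layer of real values with a nodata
mask; it is the spatial currency of every other module. Two file dialects
are supported: single-band float32 GeoTIFF and ESRI ASCII grid. Cells are
square, coordinates refer to cell centers, row 0 is the northern edge, and
a cell owns the half-open square ``[x, x + cell_size)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "CRSKind",
    "GridGeometry",
    "Grid",
    "RasterFormatError",
    "UnsupportedGeometryError",
    "read_raster",
    "write_raster",
    "bicubic_upsample",
    "km_to_map_units",
    "KM_PER_DEGREE",
]

#: Spherical-Earth kilometres per degree of latitude (radius 6371 km).
KM_PER_DEGREE = 111.19

_DEFAULT_NODATA = -9999.0


class RasterFormatError(ValueError):
    """A raster file failed to parse; the message names the offending field."""


class UnsupportedGeometryError(ValueError):
    """The raster geometry is outside the supported model (e.g. rectangular cells)."""


class CRSKind(str, Enum):
    projected_metric = "projected_metric"
    geographic_degrees = "geographic_degrees"


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular square-cell raster.

    ``x_origin``/``y_origin`` are the west and north *edges* of the grid in
    map units; ``cell_size`` is the (square) cell edge length.
    """

    n_rows: int
    n_cols: int
    x_origin: float
    y_origin: float
    cell_size: float
    crs_kind: CRSKind = CRSKind.projected_metric

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise UnsupportedGeometryError(
                f"grid must be at least 1x1, got {self.n_rows}x{self.n_cols}"
            )
        if not (self.cell_size > 0):
            raise UnsupportedGeometryError(f"cell_size must be > 0, got {self.cell_size}")

    # -- coordinate helpers ------------------------------------------------

    @property
    def x_max(self) -> float:
        return self.x_origin + self.n_cols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.y_origin - self.n_rows * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x of column centers, y of row centers)."""
        xs = self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def rowcol_of(self, x, y):
        """Row/column of the cell owning point(s) (x, y); may fall outside the grid."""
        col = np.floor((np.asarray(x, dtype=float) - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - np.asarray(y, dtype=float)) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.rowcol_of(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def aligned_with(self, other: "GridGeometry") -> bool:
        return self == other


@dataclass
class Grid:
    """One raster layer: geometry + values + nodata mask.

    Masked cells are excluded from all statistics; their stored value is
    meaningless. ``values`` is float64 internally.
    """

    geometry: GridGeometry
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match geometry "
                f"({self.geometry.n_rows}, {self.geometry.n_cols})"
            )
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")
            self.mask = self.mask | ~np.isfinite(self.values)
        # keep masked cells numerically benign
        self.values = np.where(self.mask, 0.0, self.values)

    def copy(self) -> "Grid":
        return Grid(self.geometry, self.values.copy(), self.mask.copy())

    def unmasked(self) -> np.ndarray:
        return self.values[~self.mask]

    def with_values(self, values: np.ndarray) -> "Grid":
        return Grid(self.geometry, values, self.mask.copy())

    def equals(self, other: "Grid", atol: float = 1e-6) -> bool:
        return (
            self.geometry == other.geometry
            and bool(np.array_equal(self.mask, other.mask))
            and bool(np.allclose(self.unmasked(), other.unmasked(), atol=atol))
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_ASCII_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_esri_ascii(path: Path, crs_kind: CRSKind) -> Grid:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASCII_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise RasterFormatError(f"{path}: bad value for header field {parts[0]}") from exc
            n_header += 1
        else:
            break
    for key in _ASCII_KEYS:
        if key not in header:
            raise RasterFormatError(f"{path}: missing required header field {key.upper()}")
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if header["cellsize"] <= 0:
        raise UnsupportedGeometryError(f"{path}: CELLSIZE must be > 0, got {header['cellsize']}")
    try:
        body = np.loadtxt(lines[n_header:], dtype=float, ndmin=2)
    except ValueError as exc:
        raise RasterFormatError(f"{path}: malformed grid body") from exc
    if body.shape != (n_rows, n_cols):
        raise RasterFormatError(
            f"{path}: body shape {body.shape} does not match NROWS/NCOLS ({n_rows}, {n_cols})"
        )
    geom = GridGeometry(
        n_rows=n_rows,
        n_cols=n_cols,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        crs_kind=crs_kind,
    )
    mask = np.isclose(body, nodata) | ~np.isfinite(body)
    return Grid(geom, np.where(mask, 0.0, body), mask)


def _write_esri_ascii(grid: Grid, path: Path) -> None:
    g = grid.geometry
    body = np.where(grid.mask, _DEFAULT_NODATA, grid.values)
    with open(path, "w") as fh:
        fh.write(f"NCOLS {g.n_cols}\n")
        fh.write(f"NROWS {g.n_rows}\n")
        fh.write(f"XLLCORNER {g.x_origin!r}\n")
        fh.write(f"YLLCORNER {g.y_min!r}\n")
        fh.write(f"CELLSIZE {g.cell_size!r}\n")
        fh.write(f"NODATA_value {_DEFAULT_NODATA}\n")
        np.savetxt(fh, body, fmt="%.10g")


# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# Minimal GeoKey directory: raster type = PixelIsArea, model type 1 (projected)
# or 2 (geographic).
def _geokeys(crs_kind: CRSKind) -> list[int]:
    model = 2 if crs_kind is CRSKind.geographic_degrees else 1
    return [1, 1, 0, 2, 1024, 0, 1, model, 1025, 0, 1, 1]


def _read_geotiff(path: Path) -> Grid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        if values.ndim != 2:
            raise UnsupportedGeometryError(f"{path}: only single-band rasters are supported")
        tags = {t.code: t.value for t in page.tags.values()}
    if _TAG_MODEL_PIXEL_SCALE not in tags:
        raise RasterFormatError(f"{path}: missing ModelPixelScale tag")
    if _TAG_MODEL_TIEPOINT not in tags:
        raise RasterFormatError(f"{path}: missing ModelTiepoint tag")
    sx, sy = float(tags[_TAG_MODEL_PIXEL_SCALE][0]), float(tags[_TAG_MODEL_PIXEL_SCALE][1])
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise UnsupportedGeometryError(f"{path}: non-square cells ({sx} x {sy}) are unsupported")
    if sx <= 0:
        raise UnsupportedGeometryError(f"{path}: cell size must be > 0, got {sx}")
    tie = tags[_TAG_MODEL_TIEPOINT]
    # tiepoint: raster (i, j, k) -> model (x, y, z); we require the (0,0) corner
    x_origin = float(tie[3]) - float(tie[0]) * sx
    y_origin = float(tie[4]) + float(tie[1]) * sy
    crs_kind = CRSKind.projected_metric
    geokeys = tags.get(_TAG_GEO_KEY_DIRECTORY)
    if geokeys is not None:
        keys = list(geokeys)
        for i in range(4, len(keys) - 3, 4):
            if keys[i] == 1024 and keys[i + 3] == 2:
                crs_kind = CRSKind.geographic_degrees
    nodata = tags.get(_TAG_GDAL_NODATA)
    mask = ~np.isfinite(values)
    if nodata is not None:
        try:
            nodata_val = float(str(nodata).strip())
        except ValueError as exc:
            raise RasterFormatError(f"{path}: unparseable GDAL nodata tag {nodata!r}") from exc
        if math.isnan(nodata_val):
            mask |= np.isnan(values)
        else:
            mask |= np.isclose(values, nodata_val)
    geom = GridGeometry(
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        x_origin=x_origin,
        y_origin=y_origin,
        cell_size=sx,
        crs_kind=crs_kind,
    )
    return Grid(geom, np.where(mask, 0.0, values), mask)


def _write_geotiff(grid: Grid, path: Path) -> None:
    import tifffile

    g = grid.geometry
    body = np.where(grid.mask, _DEFAULT_NODATA, grid.values).astype(np.float32)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.x_origin, g.y_origin, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", 12, tuple(_geokeys(g.crs_kind))),
        (_TAG_GDAL_NODATA, "s", 0, str(_DEFAULT_NODATA)),
    ]
    tifffile.imwrite(path, body, extratags=extratags)


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    if suffix in (".asc", ".txt", ".grd"):
        return "esri_ascii"
    raise RasterFormatError(f"cannot infer raster format from suffix of {path}")


def read_raster(path, format: str | None = None, crs_kind: CRSKind = CRSKind.projected_metric) -> Grid:
    """Read a single-band raster as a :class:`Grid`.

    ``format`` is ``"geotiff"`` or ``"esri_ascii"``; inferred from the file
    suffix when omitted. For ESRI ASCII, which carries no CRS metadata,
    ``crs_kind`` declares the coordinate interpretation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    fmt = format or _detect_format(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    if fmt == "esri_ascii":
        return _read_esri_ascii(path, crs_kind)
    raise ValueError(f"unknown raster format {fmt!r}")


def write_raster(grid: Grid, path, format: str | None = None) -> None:
    """Write a :class:`Grid`; masked cells become the dialect's nodata value."""
    path = Path(path)
    fmt = format or _detect_format(path)
    try:
        if fmt == "geotiff":
            _write_geotiff(grid, path)
        elif fmt == "esri_ascii":
            _write_esri_ascii(grid, path)
        else:
            raise ValueError(f"unknown raster format {fmt!r}")
    except OSError as exc:
        raise OSError(f"failed writing raster to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Bicubic (Catmull–Rom) resampling
# ---------------------------------------------------------------------------


def _catmull_rom_weights(t: np.ndarray) -> np.ndarray:
    """Keys cubic convolution weights (a = -1/2) for the 4-node stencil.

    ``t`` in [0, 1) is the fractional offset past node 1 of the stencil
    (nodes -1, 0, 1, 2 relative to the floor node). Returns shape (4, *t.shape).
    The kernel interpolates: at t = 0 all weight is on node 0.
    """
    t = np.asarray(t, dtype=float)
    t2 = t * t
    t3 = t2 * t
    w0 = 0.5 * (-t3 + 2 * t2 - t)
    w1 = 0.5 * (3 * t3 - 5 * t2 + 2)
    w2 = 0.5 * (-3 * t3 + 4 * t2 + t)
    w3 = 0.5 * (t3 - t2)
    return np.stack([w0, w1, w2, w3])


def _interp_axis_positions(fine_coords: np.ndarray, origin_center: float, spacing: float, n: int):
    """Fractional node index of each fine coordinate along one coarse axis."""
    u = (fine_coords - origin_center) / spacing
    i0 = np.floor(u).astype(int)
    t = u - i0
    # stencil node indices, edge-replicated
    idx = np.clip(i0[None, :] + np.arange(-1, 3)[:, None], 0, n - 1)
    w = _catmull_rom_weights(t)
    return idx, w


def catmull_rom_at(coarse: Grid, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Evaluate the Catmull–Rom surface of ``coarse`` at arbitrary points."""
    g = coarse.geometry
    xs0 = g.x_origin + 0.5 * g.cell_size
    ys0 = g.y_origin - 0.5 * g.cell_size
    col_idx, wx = _interp_axis_positions(np.asarray(x, float), xs0, g.cell_size, g.n_cols)
    # y decreases with row index
    row_idx, wy = _interp_axis_positions(-np.asarray(y, float), -ys0, g.cell_size, g.n_rows)
    vals = coarse.values
    out = np.zeros(np.asarray(x).shape, dtype=float)
    for a in range(4):
        row_a = row_idx[a]
        inner = np.zeros_like(out)
        for b in range(4):
            inner += wx[b] * vals[row_a, col_idx[b]]
        out += wy[a] * inner
    return out


def bicubic_upsample(coarse: Grid, target: GridGeometry) -> Grid:
    """Resample ``coarse`` onto ``target`` with interpolating bicubic convolution.

    The Catmull–Rom kernel is value-preserving at coarse nodes and reproduces
    linear ramps exactly on the interior; the grid edge is handled by node
    replication. The coarse grid must be complete (no masked interior cells)
    and at least 2x2.
    """
    if coarse.geometry.n_rows < 2 or coarse.geometry.n_cols < 2:
        raise UnsupportedGeometryError("bicubic upsampling requires a coarse grid of at least 2x2")
    if coarse.mask.any():
        raise ValueError("bicubic upsampling requires a complete (unmasked) coarse grid")
    xs, ys = target.cell_centers()
    xg, yg = np.meshgrid(xs, ys)
    fine = catmull_rom_at(coarse, xg.ravel(), yg.ravel()).reshape(target.n_rows, target.n_cols)
    return Grid(target, fine, np.zeros((target.n_rows, target.n_cols), dtype=bool))


def km_to_map_units(distance_km: float, latitude: float = 0.0, crs_kind: CRSKind = CRSKind.projected_metric) -> float:
    """Convert kilometres to map units.

    Projected-metric grids use metres (km x 1000). Geographic grids return
    degrees of latitude (km / 111.19 on a spherical Earth); the caller applies
    the cos(latitude) longitude scaling per axis.
    """
    if abs(latitude) >= 90:
        raise ValueError(f"|latitude| must be < 90, got {latitude}")
    if CRSKind(crs_kind) is CRSKind.projected_metric:
        return distance_km * 1000.0
    return distance_km / KM_PER_DEGREE
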