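"""Landscape resistance rasters.

A :class:`ResistanceRaster` is a georeferenced grid of movement-resistance
values in ``[0, 1]``: 0 means free movement (full conductance), 1 means
impassable terrain.  The extreme binary case (only 0s and 1s) confines a
walker to the zero-resistance component, e.g. a fish in a river; a raster
may also be omitted entirely, which is homogeneous space.

Conventions
-----------
* Pixels are half-open cells ``[x0 + j*c, x0 + (j+1)*c) x [y0 + i*c,
  y0 + (i+1)*c)`` with ``c`` the cell size; ``values[0, 0]`` is the
  *top-left* cell in file order while ``(origin_x, origin_y)`` is the
  lower-left corner of the extent, matching common raster formats.
* Any point outside the extent is treated as resistance 1, so a simulated
  walker can never leave the raster.
* NoData cells become resistance 1 on read: unknown terrain is impassable,
  the conservative choice for a constrained walker.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import shape as _geojson_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "ResistanceRaster",
    "ShapeSpec",
    "raster_from_shapes",
    "read_raster",
    "write_raster",
    "read_shapes",
    "resistance_at",
]

logger = logging.getLogger(__name__)

_NODATA = -9999.0

# private GeoTIFF tag codes used for georeferencing
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922


@dataclass(frozen=True)
class ResistanceRaster:
    """Grid of resistance values in [0, 1] on a square-pixel georeference.

    Parameters
    ----------
    values
        2-D float array, row 0 at the top (file order).
    origin_x, origin_y
        Map coordinates of the lower-left corner of the extent.
    cell_size
        Side length of the (square) pixels, in map units.
    crs_tag
        Opaque coordinate-system identifier, stored pass-through only.
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    crs_tag: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2 or vals.shape[0] < 1 or vals.shape[1] < 1:
            raise ValueError("raster values must be a non-empty 2-D grid")
        if not np.isfinite(vals).all():
            raise ValueError("raster contains non-finite values; replace NoData before construction")
        lo, hi = float(vals.min()), float(vals.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(
                f"resistance values must lie in [0, 1]; found range [{lo:g}, {hi:g}]"
            )
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        object.__setattr__(self, "values", vals)

    @property
    def nrow(self) -> int:
        return self.values.shape[0]

    @property
    def ncol(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in map units."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.ncol * self.cell_size,
            self.origin_y + self.nrow * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) map-unit coordinate grids of all cell centers."""
        xs = self.origin_x + (np.arange(self.ncol) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.nrow) + 0.5) * self.cell_size
        # row 0 is the top of the grid
        return np.meshgrid(xs, ys[::-1])

    def __eq__(self, other: object) -> bool:  # dataclass eq breaks on arrays
        if not isinstance(other, ResistanceRaster):
            return NotImplemented
        return (
            np.array_equal(self.values, other.values)
            and self.origin_x == other.origin_x
            and self.origin_y == other.origin_y
            and self.cell_size == other.cell_size
            and self.crs_tag == other.crs_tag
        )


@dataclass(frozen=True)
class ShapeSpec:
    """A vector feature carrying a resistance value.

    Polylines are rasterized as corridors of total width ``2 * buffer_width``;
    for polygons ``buffer_width`` is normally 0 (the polygon itself is used).
    """

    geometry: BaseGeometry
    resistance: float
    buffer_width: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.resistance <= 1.0:
            raise ValueError("shape resistance must be in [0, 1]")
        if self.buffer_width < 0:
            raise ValueError("buffer_width must be >= 0")

    def effective_geometry(self) -> BaseGeometry:
        if self.buffer_width > 0:
            return self.geometry.buffer(self.buffer_width, quad_segs=16)
        return self.geometry


def raster_from_shapes(
    shapes: list[ShapeSpec],
    background_resistance: float,
    extent: tuple[float, float, float, float],
    cell_size: float,
    crs_tag: str = "",
) -> ResistanceRaster:
    """Rasterize and overlay vector features onto a background resistance.

    Each cell takes the resistance of the *last* shape in the list whose
    (buffered) geometry covers the cell center; untouched cells keep
    ``background_resistance``.  Rasterization is deterministic.
    """
    xmin, ymin, xmax, ymax = map(float, extent)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("extent must be non-degenerate (xmax > xmin, ymax > ymin)")
    if not cell_size > 0:
        raise ValueError("cell_size must be positive")
    if not 0.0 <= background_resistance <= 1.0:
        raise ValueError("background_resistance must be in [0, 1]")

    ncol = max(1, int(math.ceil((xmax - xmin) / cell_size)))
    nrow = max(1, int(math.ceil((ymax - ymin) / cell_size)))
    values = np.full((nrow, ncol), background_resistance, dtype=np.float64)

    xs = xmin + (np.arange(ncol) + 0.5) * cell_size
    ys_top_down = ymin + (np.arange(nrow)[::-1] + 0.5) * cell_size
    X, Y = np.meshgrid(xs, ys_top_down)

    from shapely.geometry import box

    extent_box = box(xmin, ymin, xmax, ymax)
    for i, spec in enumerate(shapes):
        geom = spec.effective_geometry()
        if not geom.intersects(extent_box):
            logger.warning("shape %d lies outside the raster extent; ignored", i)
            continue
        mask = shapely.intersects_xy(geom, X.ravel(), Y.ravel()).reshape(nrow, ncol)
        values[mask] = spec.resistance

    return ResistanceRaster(values, xmin, ymin, cell_size, crs_tag=crs_tag)


def resistance_at(raster: ResistanceRaster | None, x, y):
    """Resistance of the pixel containing map point(s) ``(x, y)``.

    Points outside the raster extent return 1 (impassable boundary).  With
    ``raster=None`` (homogeneous space) the result is 0 everywhere.
    Accepts scalars or array-likes and broadcasts.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if raster is None:
        out = np.zeros(np.broadcast(x, y).shape)
        return float(out) if out.ndim == 0 else out
    col = np.floor((x - raster.origin_x) / raster.cell_size).astype(np.int64)
    row_b = np.floor((y - raster.origin_y) / raster.cell_size).astype(np.int64)
    inside = (col >= 0) & (col < raster.ncol) & (row_b >= 0) & (row_b < raster.nrow)
    out = np.ones(np.broadcast(x, y).shape, dtype=np.float64)
    if out.ndim == 0:
        if inside:
            return float(raster.values[raster.nrow - 1 - int(row_b), int(col)])
        return 1.0
    rows = raster.nrow - 1 - row_b[inside]
    out[inside] = raster.values[rows, col[inside]]
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_raster(raster: ResistanceRaster, path: str | Path) -> None:
    """Write a raster as GeoTIFF (.tif/.tiff) or ESRI ASCII grid (.asc/.txt)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        _write_geotiff(raster, path)
    elif suffix in (".asc", ".txt", ".grd"):
        _write_ascii_grid(raster, path)
    else:
        raise ValueError(f"unsupported raster format: {suffix!r} (use .tif or .asc)")


def read_raster(path: str | Path) -> ResistanceRaster:
    """Read a GeoTIFF or ESRI ASCII grid resistance raster.

    NoData cells become resistance 1.  Values outside [0, 1] after NoData
    substitution raise a validation error (no silent rescaling of, e.g.,
    0-255 encoded rasters).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return _read_geotiff(path)
    if suffix in (".asc", ".txt", ".grd"):
        return _read_ascii_grid(path)
    raise ValueError(f"unsupported raster format: {suffix!r} (use .tif or .asc)")


def _write_geotiff(raster: ResistanceRaster, path: Path) -> None:
    ytop = raster.origin_y + raster.nrow * raster.cell_size
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (raster.cell_size, raster.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, raster.origin_x, ytop, 0.0)),
    ]
    tifffile.imwrite(
        path,
        raster.values.astype(np.float64),
        extratags=extratags,
        description=raster.crs_tag,
        metadata=None,  # keep the description tag as the bare crs string
    )


def _read_geotiff(path: Path) -> ResistanceRaster:
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray().astype(np.float64)
            tags = {tag.code: tag.value for tag in page.tags.values()}
            crs_tag = str(tags.get(270, "") or "")
    except (tifffile.TiffFileError, OSError) as exc:
        raise OSError(f"could not read GeoTIFF {path}: {exc}") from exc
    if values.ndim != 2:
        raise ValueError("multi-band rasters are not supported")
    scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
    tiepoint = tags.get(_TAG_MODEL_TIEPOINT)
    if scale is None or tiepoint is None:
        raise ValueError(f"GeoTIFF {path} lacks georeferencing tags")
    cell = float(scale[0])
    if not math.isclose(float(scale[0]), float(scale[1]), rel_tol=1e-9):
        raise ValueError("only square pixels are supported")
    x0 = float(tiepoint[3])
    ytop = float(tiepoint[4])
    values = np.where(np.isfinite(values), values, 1.0)  # NaN NoData -> impassable
    _validate_range(values, path)
    nrow = values.shape[0]
    return ResistanceRaster(values, x0, ytop - nrow * cell, cell, crs_tag=crs_tag)


def _write_ascii_grid(raster: ResistanceRaster, path: Path) -> None:
    header = (
        f"ncols {raster.ncol}\n"
        f"nrows {raster.nrow}\n"
        f"xllcorner {raster.origin_x!r}\n"
        f"yllcorner {raster.origin_y!r}\n"
        f"cellsize {raster.cell_size!r}\n"
        f"NODATA_value {_NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in raster.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    if raster.crs_tag:
        path.with_suffix(".prj").write_text(raster.crs_tag)


def _read_ascii_grid(path: Path) -> ResistanceRaster:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    try:
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                key = parts[0].lower()
                if not data_lines and key in (
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value", "xllcenter", "yllcenter",
                ):
                    header[key] = float(parts[1])
                else:
                    data_lines.append(line)
    except OSError as exc:
        raise OSError(f"could not read ASCII grid {path}: {exc}") from exc
    for required in ("ncols", "nrows", "cellsize"):
        if required not in header:
            raise ValueError(f"ASCII grid {path} missing header field {required!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        x0, y0 = header["xllcorner"], header["yllcorner"]
    else:  # cell-center registration
        x0 = header["xllcenter"] - cell / 2
        y0 = header["yllcenter"] - cell / 2
    values = np.loadtxt(data_lines, dtype=np.float64)
    values = np.atleast_2d(values)
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"ASCII grid {path}: data shape {values.shape} does not match header ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, 1.0, values)
    values = np.where(np.isfinite(values), values, 1.0)
    _validate_range(values, path)
    prj = path.with_suffix(".prj")
    crs_tag = prj.read_text().strip() if prj.exists() else ""
    return ResistanceRaster(values, x0, y0, cell, crs_tag=crs_tag)


def _validate_range(values: np.ndarray, path: Path) -> None:
    lo, hi = float(values.min()), float(values.max())
    if lo < 0.0 or hi > 1.0:
        raise ValueError(
            f"raster {path} has values in [{lo:g}, {hi:g}], outside the required "
            "[0, 1] resistance range; rescale it explicitly before use"
        )


def read_shapes(path: str | Path, resistance: float, buffer_width: float = 0.0) -> list[ShapeSpec]:
    """Read features from a GeoJSON file into :class:`ShapeSpec` objects.

    A per-feature property ``resistance`` (and optionally ``buffer_width``)
    overrides the supplied defaults.
    """
    path = Path(path)
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        features = gj["features"]
    elif gj.get("type") == "Feature":
        features = [gj]
    else:  # bare geometry
        features = [{"type": "Feature", "geometry": gj, "properties": {}}]
    specs = []
    for feat in features:
        props = feat.get("properties") or {}
        specs.append(
            ShapeSpec(
                geometry=_geojson_shape(feat["geometry"]),
                resistance=float(props.get("resistance", resistance)),
                buffer_width=float(props.get("buffer_width", buffer_width)),
            )
        )
    return specs
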