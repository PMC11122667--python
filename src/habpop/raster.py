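"""Habitat-preference rasters, 685-level quantization, and per-bin histograms.

A habitat-preference raster holds species-distribution-model output in
``[0, 1]`` per cell.  The continuous preference ``h`` is discretized onto 685
equispaced levels (bin indices ``0 .. 684``), the resolution at which the
diffusion correction and the habitat-preference/population curves operate.

Supported encodings are the Esri ASCII grid (``.asc``) and GeoTIFF (via
``tifffile``, reading the ModelPixelScale/ModelTiepoint/GDAL_NODATA tags).
Region masks are either boolean arrays co-registered with the raster or
polygons (GeoJSON / shapely geometry) rasterized by center-point inclusion.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
from shapely import contains_xy
from shapely.geometry import mapping as geom_mapping, shape as geom_shape
from shapely.geometry.base import BaseGeometry

from .errors import FormatError, UnmappedSpotError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .detections import Spot

log = logging.getLogger(__name__)

#: Number of habitat-preference levels (bin indices 0..684).
N_BINS = 685

_GEOTIFF_PIXEL_SCALE = 33550
_GEOTIFF_TIEPOINT = 33922
_GDAL_NODATA = 42113


@dataclass
class HabitatRaster:
    """A rectangular grid of habitat-preference values in ``[0, 1]``.

    ``values`` is stored row 0 = northernmost row; missing cells are NaN.
    ``xll``/``yll`` locate the lower-left corner of the grid in degrees.
    """

    values: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0
    crs_tag: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("raster values must be a 2-D grid")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValidationError(
                "habitat preference values outside [0, 1]: "
                f"range ({finite.min():g}, {finite.max():g})"
            )

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def ytop(self) -> float:
        return self.yll + self.nrows * self.cellsize

    def index_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Grid cell containing ``(lon, lat)``; half-open cells, points on an
        edge belong to the higher-index cell.  None when outside the extent."""
        col = math.floor((lon - self.xll) / self.cellsize)
        row = math.floor((self.ytop - lat) / self.cellsize)
        if 0 <= row < self.nrows and 0 <= col < self.ncols:
            return row, col
        return None

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) coordinate arrays of all cell centers, same shape as
        ``values``."""
        cs = self.cellsize
        lon = self.xll + (np.arange(self.ncols) + 0.5) * cs
        lat = self.ytop - (np.arange(self.nrows) + 0.5) * cs
        return np.meshgrid(lon, lat)

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class HabitatHistogram:
    """Pixel counts per habitat bin for a raster (optionally masked)."""

    counts: np.ndarray
    region_tag: str = "map"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (N_BINS,):
            raise ValidationError(f"histogram must have {N_BINS} bins")
        if np.any(self.counts < 0):
            raise ValidationError("histogram counts must be nonnegative")

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    @staticmethod
    def h_values() -> np.ndarray:
        """Habitat-preference value at each bin center (bin / 684)."""
        return np.arange(N_BINS) / (N_BINS - 1)


def quantize(h):
    """Bin index of preference ``h``: nearest of the 685 equispaced levels.

    ``quantize(0) = 0``, ``quantize(1) = 684``; monotone in ``h``.
    """
    arr = np.asarray(h, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValidationError("habitat preference must lie in [0, 1]")
    idx = np.floor(arr * (N_BINS - 1) + 0.5).astype(int)
    return int(idx) if np.ndim(h) == 0 else idx


def _parse_asc(path: Path) -> HabitatRaster:
    header: dict[str, float] = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0][0].isalpha():
            header[parts[0].lower()] = float(parts[1])
            data_start = i + 1
        else:
            break
    required = {"ncols", "nrows", "cellsize"}
    if not required <= header.keys():
        raise FormatError(f"{path}: missing ASC header keys {required - header.keys()}")
    cs = header["cellsize"]
    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - cs / 2.0
    else:
        raise FormatError(f"{path}: missing xllcorner/xllcenter")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - cs / 2.0
    else:
        raise FormatError(f"{path}: missing yllcorner/yllcenter")
    nodata = header.get("nodata_value", -9999.0)
    try:
        values = np.loadtxt(lines[data_start:], dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: could not parse grid values: {exc}") from exc
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise FormatError(
            f"{path}: grid shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    values = np.where(values == nodata, np.nan, values)
    return HabitatRaster(values=values, xll=xll, yll=yll, cellsize=cs, nodata=nodata)


def _parse_geotiff(path: Path) -> HabitatRaster:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        scale = tags.get(_GEOTIFF_PIXEL_SCALE)
        tie = tags.get(_GEOTIFF_TIEPOINT)
        if scale is None or tie is None:
            raise FormatError(f"{path}: GeoTIFF lacks ModelPixelScale/ModelTiepoint tags")
        sx, sy = float(scale.value[0]), float(scale.value[1])
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise FormatError(f"{path}: anisotropic pixels ({sx} x {sy}) unsupported")
        i, j, _, x, y, _ = (float(v) for v in tie.value[:6])
        xll = x - i * sx
        ytop = y + j * sy
        nodata = -9999.0
        nd = tags.get(_GDAL_NODATA)
        if nd is not None:
            nodata = float(str(nd.value))
        values = np.where(values == nodata, np.nan, values)
        return HabitatRaster(
            values=values,
            xll=xll,
            yll=ytop - values.shape[0] * sx,
            cellsize=sx,
            nodata=nodata,
        )


def read_raster(path: str | Path) -> HabitatRaster:
    """Read a habitat-preference raster from an ``.asc`` grid or GeoTIFF."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"raster file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in {".asc", ".txt"}:
        return _parse_asc(path)
    if suffix in {".tif", ".tiff"}:
        return _parse_geotiff(path)
    raise FormatError(f"unsupported raster format {suffix!r} (use .asc or .tif)")


def write_asc(raster: HabitatRaster, path: str | Path) -> None:
    """Write a raster as an Esri ASCII grid."""
    path = Path(path)
    values = np.where(np.isfinite(raster.values), raster.values, raster.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xll:.10g}\n")
        fh.write(f"yllcorner {raster.yll:.10g}\n")
        fh.write(f"cellsize {raster.cellsize:.10g}\n")
        fh.write(f"NODATA_value {raster.nodata:g}\n")
        np.savetxt(fh, values, fmt="%.8g")


def write_geotiff(raster: HabitatRaster, path: str | Path) -> None:
    """Write a raster as a GeoTIFF with minimal georeferencing tags."""
    import tifffile

    values = np.where(np.isfinite(raster.values), raster.values, raster.nodata)
    nodata_str = f"{raster.nodata:g}"
    tifffile.imwrite(
        str(path),
        values.astype(np.float64),
        extratags=[
            (_GEOTIFF_PIXEL_SCALE, "d", 3, (raster.cellsize, raster.cellsize, 0.0)),
            (_GEOTIFF_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, raster.xll, raster.ytop, 0.0)),
            (_GDAL_NODATA, "s", len(nodata_str) + 1, nodata_str),
        ],
    )


def mask_from_polygon(raster: HabitatRaster, geom: BaseGeometry) -> np.ndarray:
    """Boolean mask of raster cells whose center lies inside ``geom``."""
    lon, lat = raster.cell_centers()
    return contains_xy(geom, lon, lat)


def read_region_geojson(path: str | Path) -> BaseGeometry:
    """Load the (union of) geometry in a GeoJSON file."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") == "FeatureCollection":
        geoms = [geom_shape(f["geometry"]) for f in doc["features"]]
        if not geoms:
            raise FormatError(f"{path}: empty FeatureCollection")
        out = geoms[0]
        for g in geoms[1:]:
            out = out.union(g)
        return out
    if doc.get("type") == "Feature":
        return geom_shape(doc["geometry"])
    return geom_shape(doc)


def write_region_geojson(geom: BaseGeometry, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "Feature", "properties": {}, "geometry": geom_mapping(geom)}, fh)


def _coerce_mask(raster: HabitatRaster, mask) -> np.ndarray | None:
    if mask is None:
        return None
    if isinstance(mask, BaseGeometry):
        return mask_from_polygon(raster, mask)
    mask = np.asarray(mask)
    if mask.shape != raster.values.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not align with raster {raster.values.shape}"
        )
    return mask.astype(bool)


def histogram(raster: HabitatRaster, mask=None, region_tag: str = "map") -> HabitatHistogram:
    """Pixel count per habitat bin over the raster (or a masked region).

    No-data cells are excluded.  ``mask`` may be a co-registered boolean
    array or a polygon geometry (rasterized by center-point inclusion).
    """
    sel = raster.valid_mask()
    m = _coerce_mask(raster, mask)
    if m is not None:
        sel = sel & m
    bins = quantize(raster.values[sel])
    counts = np.bincount(bins, minlength=N_BINS)
    return HabitatHistogram(counts=counts, region_tag=region_tag)


def spot_habitat(raster: HabitatRaster, spot: "Spot"):
    """Habitat bin of the raster cell containing the spot centroid.

    Raises :class:`UnmappedSpotError` for centroids outside the extent or on
    no-data cells.
    """
    lon, lat = spot.centroid
    idx = raster.index_of(lon, lat)
    if idx is None:
        raise UnmappedSpotError(f"spot {spot.spot_id} at ({lon:.5f}, {lat:.5f}) outside raster")
    value = raster.values[idx]
    if not np.isfinite(value):
        raise UnmappedSpotError(f"spot {spot.spot_id} falls on a no-data cell {idx}")
    return quantize(float(value))


def assign_bins(raster: HabitatRaster, spots: "list[Spot]") -> "list[Spot]":
    """Fill ``habitat_bin`` for each spot; unmapped spots are dropped with a
    logged warning."""
    kept = []
    for spot in spots:
        try:
            spot.habitat_bin = spot_habitat(raster, spot)
            kept.append(spot)
        except UnmappedSpotError as exc:
            log.warning("excluding spot: %s", exc)
    return kept
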