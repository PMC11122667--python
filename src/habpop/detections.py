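"""GPS detection records and their aggregation into fixed-area spots.

A detection record is one reported observation (camera-trap image, transect
sighting, or direct sighting) carrying a location and the number of
individuals seen (>= 1).  Records are grouped by home range — single-linkage
clustering under great-circle distance with an 800 m cutoff, the radius of a
2 km² circle — and the clusters are assigned to a rectangular grid of
0.0131°-square spots aligned with the habitat raster.  A spot's signal count
``s`` is the sum of the reported individual counts of its member records.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

#: Mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

#: Home-range grouping radius (m): radius of a 2 km² circle, to the nearest 100 m.
DEFAULT_RADIUS_M = 800.0

#: Spot grid cell size in decimal degrees.
DEFAULT_CELL_DEG = 0.0131

#: Fixed spot area (km²) adopted for every grid cell.
SPOT_AREA_KM2 = 1.143

VALID_SOURCES = ("camera_trap", "transect", "sighting")

_COLUMNS = ["longitude", "latitude", "count", "source", "date"]


@dataclass
class DetectionRecord:
    longitude: float
    latitude: float
    count: int
    source: str = "sighting"
    date: str | None = None

    def __post_init__(self) -> None:
        if not (-180.0 <= self.longitude <= 180.0 and -90.0 <= self.latitude <= 90.0):
            raise ValidationError(
                f"coordinates ({self.longitude}, {self.latitude}) out of range"
            )
        if self.count < 1:
            raise ValidationError(f"count must be >= 1, got {self.count}")
        if self.source not in VALID_SOURCES:
            raise ValidationError(f"source {self.source!r} not one of {VALID_SOURCES}")


@dataclass
class Cluster:
    """Records grouped within the home-range radius (single linkage)."""

    records: list[DetectionRecord]

    @property
    def centroid(self) -> tuple[float, float]:
        """Count-weighted mean of member coordinates."""
        w = np.array([r.count for r in self.records], dtype=float)
        lon = np.array([r.longitude for r in self.records])
        lat = np.array([r.latitude for r in self.records])
        return float((lon * w).sum() / w.sum()), float((lat * w).sum() / w.sum())

    @property
    def signals(self) -> int:
        return sum(r.count for r in self.records)


@dataclass
class Spot:
    """A fixed-area grid cell with an aggregated signal count."""

    spot_id: str
    centroid: tuple[float, float]
    cell_index: tuple[int, int]
    signals: int
    habitat_bin: int | None = None
    area_km2: float = SPOT_AREA_KM2
    records: list[DetectionRecord] = field(default_factory=list, repr=False)


def read_detections(path: str | Path) -> list[DetectionRecord]:
    """Parse a comma-separated detections table.

    Required columns: longitude, latitude, count, source; optional: date.
    Invalid rows raise a :class:`ValidationError` naming their line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"detections file not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"date": "string"})
    except Exception as exc:
        raise FormatError(f"{path}: not parseable as CSV: {exc}") from exc
    missing = {"longitude", "latitude", "count", "source"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    records: list[DetectionRecord] = []
    bad: list[str] = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            date = row.get("date")
            records.append(
                DetectionRecord(
                    longitude=float(row["longitude"]),
                    latitude=float(row["latitude"]),
                    count=int(row["count"]),
                    source=str(row["source"]),
                    date=None if pd.isna(date) else str(date),
                )
            )
        except (ValidationError, ValueError) as exc:
            bad.append(f"line {line_no}: {exc}")
    if bad:
        raise ValidationError(f"{path}: {len(bad)} invalid rows:\n" + "\n".join(bad))
    return records


def write_detections(records: list[DetectionRecord], path: str | Path) -> None:
    """Write records as a comma-separated table (inverse of read_detections)."""
    df = pd.DataFrame(
        [
            (r.longitude, r.latitude, r.count, r.source, r.date if r.date else "")
            for r in records
        ],
        columns=_COLUMNS,
    )
    df.to_csv(path, index=False)


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in meters on a spherical Earth."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * 1000.0 * np.arcsin(np.sqrt(a))


def _unit_sphere_xyz(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lam, phi = np.radians(lon), np.radians(lat)
    return np.column_stack(
        (np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi))
    )


def cluster_records(
    records: list[DetectionRecord], radius_m: float = DEFAULT_RADIUS_M
) -> list[Cluster]:
    """Single-linkage clusters of records under great-circle distance.

    Two records share a cluster iff they are connected through a chain of
    pairs each strictly closer than ``radius_m``.  The pair search uses a
    k-d tree on unit-sphere coordinates (chord length maps monotonically to
    great-circle distance), then verifies each candidate pair with the
    haversine formula, so the strict-inequality criterion is exact.
    """
    if not records:
        raise ValidationError("no detection records to cluster")
    lon = np.array([r.longitude for r in records])
    lat = np.array([r.latitude for r in records])
    xyz = _unit_sphere_xyz(lon, lat)
    # chord length corresponding to the great-circle cutoff (pad for roundoff)
    chord = 2.0 * math.sin(radius_m / (2.0 * EARTH_RADIUS_KM * 1000.0))
    pairs = cKDTree(xyz).query_pairs(chord * (1.0 + 1e-9), output_type="ndarray")
    if pairs.size:
        d = haversine_m(lon[pairs[:, 0]], lat[pairs[:, 0]], lon[pairs[:, 1]], lat[pairs[:, 1]])
        pairs = pairs[d < radius_m]
    n = len(records)
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])) if len(pairs) else ((), ((), ())),
        shape=(n, n),
    )
    n_comp, labels = connected_components(graph, directed=False)
    clusters = [Cluster(records=[]) for _ in range(n_comp)]
    for rec, lab in zip(records, labels):
        clusters[lab].records.append(rec)
    # deterministic ordering independent of input permutation
    clusters.sort(key=lambda c: (c.centroid[1], c.centroid[0]))
    return clusters


def grid_spots(
    clusters: list[Cluster],
    cell_deg: float = DEFAULT_CELL_DEG,
    origin: tuple[float, float] = (0.0, 90.0),
) -> list[Spot]:
    """Assign clusters to grid cells and merge those sharing a cell.

    ``origin`` is the (west edge, north edge) of cell (0, 0); rows grow
    southward, columns eastward.  Cells are half-open: a centroid exactly on
    an edge belongs to the higher-index cell.  A spot's signal count is the
    sum of its member records' reported individual counts.
    """
    if not clusters:
        raise ValidationError("no clusters to grid")
    lon0, lat0 = origin
    cells: dict[tuple[int, int], list[Cluster]] = {}
    for cl in clusters:
        lon, lat = cl.centroid
        col = math.floor((lon - lon0) / cell_deg)
        row = math.floor((lat0 - lat) / cell_deg)
        cells.setdefault((row, col), []).append(cl)
    spots = []
    for (row, col), members in sorted(cells.items()):
        records = [r for cl in members for r in cl.records]
        merged = Cluster(records=records)
        spots.append(
            Spot(
                spot_id=f"r{row}c{col}",
                centroid=merged.centroid,
                cell_index=(row, col),
                signals=merged.signals,
                records=records,
            )
        )
    return spots


def spot_radius_check(area_km2: float) -> float:
    """Radius in meters of a circle with the given area (km²)."""
    if area_km2 <= 0:
        raise ValidationError(f"area must be > 0, got {area_km2}")
    return math.sqrt(area_km2 / math.pi) * 1000.0
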