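"""Synthetic study worlds with known ground truth.

The generator emulates the three field inputs of the pipeline:

* a spatially smooth habitat-preference raster (Gaussian random field,
  rescaled to span [0, 1] exactly);
* ground-truth groups placed by an inhomogeneous Poisson process whose
  intensity is proportional to habitat preference, each group provisioned
  with probability ``prov_ratio`` and sized from the matching log-normal
  (rounded and clamped to ``[n_min, n_max]``);
* detection records: per group, the number of *distinct* detected
  individuals is ``d ~ Binomial(size, detect_prob)``; the total signal count
  inverts the double-counting correction, ``s = round(d^(1/(1-rho)))`` so
  that ``s^(1-rho) ≈ d`` — the model's inquisitiveness assumption is exactly
  satisfiable, making parameter recovery a sharp test.  At ``rho = 1`` the
  correction is non-invertible and each detected individual instead
  contributes a geometric number of signals with mean 3.

Everything is deterministic given the seed.  The truth object (groups,
sizes, populations) is for tests only; the pipeline never reads it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .detections import DetectionRecord, write_detections
from .errors import InvalidParameterError, ValidationError
from .group_size import SpeciesParams, lognormal_shape
from .raster import HabitatRaster, write_asc, write_region_geojson

__all__ = [
    "SyntheticTruth",
    "gen_habitat",
    "gen_groups",
    "gen_detections",
    "benchmark_mask",
    "mask_to_polygon",
    "write_world",
]

#: Generator defaults: the study-scale world used throughout the tests.
DEFAULT_ROWS = 200
DEFAULT_COLS = 200
DEFAULT_SMOOTHNESS = 10.0
DEFAULT_INTENSITY = 0.013  # groups per km² at habitat preference 1
DEFAULT_DETECT_PROB = 0.2
JITTER_RADIUS_M = 400.0
MAX_RECORDS_PER_GROUP = 32
_M_PER_DEG_LAT = 111_320.0


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic world."""

    groups: list[tuple[float, float, int, bool]]  # (lon, lat, size, provisioned)
    true_rho: float
    seed: int
    params: SpeciesParams = field(default_factory=SpeciesParams)

    @property
    def true_population(self) -> int:
        return sum(g[2] for g in self.groups)

    def population_within(self, raster: HabitatRaster, mask: np.ndarray) -> int:
        """Sum of group sizes whose location falls in the masked cells."""
        total = 0
        for lon, lat, size, _ in self.groups:
            idx = raster.index_of(lon, lat)
            if idx is not None and mask[idx]:
                total += size
        return total

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "true_rho": self.true_rho,
                    "true_population": self.true_population,
                    "groups": [
                        {"lon": g[0], "lat": g[1], "size": g[2], "provisioned": g[3]}
                        for g in self.groups
                    ],
                },
                fh,
                indent=2,
            )


def gen_habitat(
    seed: int,
    rows: int = DEFAULT_ROWS,
    cols: int = DEFAULT_COLS,
    smoothness: float = DEFAULT_SMOOTHNESS,
    *,
    xll: float = 100.0,
    yll: float = 10.0,
    cellsize: float = 0.0131,
) -> HabitatRaster:
    """Smooth random habitat-preference field rescaled to [0, 1].

    ``smoothness`` is the Gaussian kernel SD in cells; larger values give a
    flatter field (constant in the limit).
    """
    if rows < 10 or cols < 10:
        raise InvalidParameterError("raster must be at least 10x10")
    rng = np.random.default_rng(seed)
    field_ = gaussian_filter(rng.standard_normal((rows, cols)), sigma=smoothness)
    lo, hi = field_.min(), field_.max()
    if hi - lo < 1e-12:
        values = np.full((rows, cols), 0.5)
    else:
        values = (field_ - lo) / (hi - lo)
    return HabitatRaster(values=values, xll=xll, yll=yll, cellsize=cellsize)


def _draw_size(rng: np.random.Generator, params: SpeciesParams, provisioned: bool) -> int:
    mean, sd = (
        (params.mean_prov, params.sd_prov)
        if provisioned
        else (params.mean_nonprov, params.sd_nonprov)
    )
    shape = lognormal_shape(mean, sd)
    size = int(round(float(rng.lognormal(shape.location, shape.scale))))
    return int(np.clip(size, params.n_min, params.n_max))


def gen_groups(
    raster: HabitatRaster,
    params: SpeciesParams | None = None,
    intensity_per_km2_at_h1: float = DEFAULT_INTENSITY,
    seed: int = 0,
    *,
    true_rho: float = 0.5,
    cell_area_km2: float = 1.143,
) -> SyntheticTruth:
    """Place groups by an inhomogeneous Poisson process ∝ habitat value."""
    if intensity_per_km2_at_h1 <= 0:
        raise InvalidParameterError("intensity must be > 0")
    params = params or SpeciesParams()
    rng = np.random.default_rng(seed)
    rates = np.where(raster.valid_mask(), raster.values, 0.0) * (
        intensity_per_km2_at_h1 * cell_area_km2
    )
    counts = rng.poisson(rates)
    n_groups = int(counts.sum())
    if n_groups == 0:
        raise ValidationError(
            "Poisson draw produced zero groups; increase intensity_per_km2_at_h1"
        )
    groups: list[tuple[float, float, int, bool]] = []
    cs = raster.cellsize
    for row, col in zip(*np.nonzero(counts)):
        for _ in range(counts[row, col]):
            lon = raster.xll + (col + rng.uniform()) * cs
            lat = raster.ytop - (row + rng.uniform()) * cs
            provisioned = bool(rng.uniform() < params.prov_ratio)
            groups.append((lon, lat, _draw_size(rng, params, provisioned), provisioned))
    return SyntheticTruth(groups=groups, true_rho=float(true_rho), seed=seed, params=params)


def _emit_records(
    rng: np.random.Generator, lon: float, lat: float, s: int
) -> list[DetectionRecord]:
    """Split a group's total signal count over jittered records.

    At most :data:`MAX_RECORDS_PER_GROUP` records are emitted; their counts
    sum to ``s`` (unit counts whenever ``s`` is small enough).
    """
    n_rec = min(s, MAX_RECORDS_PER_GROUP)
    base, extra = divmod(s, n_rec)
    counts = [base + (1 if i < extra else 0) for i in range(n_rec)]
    records = []
    for c in counts:
        r = JITTER_RADIUS_M * math.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        dlat = r * math.sin(theta) / _M_PER_DEG_LAT
        dlon = r * math.cos(theta) / (_M_PER_DEG_LAT * math.cos(math.radians(lat)))
        records.append(
            DetectionRecord(
                longitude=lon + dlon,
                latitude=lat + dlat,
                count=c,
                source="camera_trap",
            )
        )
    return records


def gen_detections(
    truth: SyntheticTruth,
    detect_prob: float = DEFAULT_DETECT_PROB,
    seed: int = 0,
) -> list[DetectionRecord]:
    """Detection records implied by the truth under the model's assumption.

    Groups with no detected individuals emit nothing.
    """
    if not (0.0 < detect_prob <= 1.0):
        raise InvalidParameterError("detect_prob must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rho = truth.true_rho
    records: list[DetectionRecord] = []
    for lon, lat, size, _ in truth.groups:
        d = int(rng.binomial(size, detect_prob))
        if d == 0:
            continue
        if rho < 1.0:
            s = max(1, int(round(d ** (1.0 / (1.0 - rho)))))
        else:
            s = int(rng.geometric(1.0 / 3.0, size=d).sum())
        records.extend(_emit_records(rng, lon, lat, s))
    if not records:
        raise ValidationError("no detections generated; increase detect_prob")
    return records


def benchmark_mask(
    raster: HabitatRaster,
    rows: int = 70,
    cols: int = 70,
    row0: int | None = None,
    col0: int | None = None,
) -> np.ndarray:
    """Benchmark sub-window as a boolean cell mask.

    By default the window of the requested size with the highest mean
    habitat preference is chosen (stride 10 scan): the benchmark emulates a
    protected sanctuary, which sits in predominantly high-preference
    habitat.  Explicit ``row0``/``col0`` place the window directly.
    """
    if rows > raster.nrows or cols > raster.ncols:
        raise ValidationError("benchmark window exceeds raster extent")
    if row0 is None or col0 is None:
        vals = np.where(raster.valid_mask(), raster.values, 0.0)
        best, best_rc = -1.0, (0, 0)
        for r in range(0, raster.nrows - rows + 1, 10):
            for c in range(0, raster.ncols - cols + 1, 10):
                m = vals[r : r + rows, c : c + cols].mean()
                if m > best:
                    best, best_rc = m, (r, c)
        row0, col0 = best_rc
    if row0 + rows > raster.nrows or col0 + cols > raster.ncols:
        raise ValidationError("benchmark window exceeds raster extent")
    mask = np.zeros(raster.values.shape, dtype=bool)
    mask[row0 : row0 + rows, col0 : col0 + cols] = True
    return mask


def mask_to_polygon(raster: HabitatRaster, mask: np.ndarray):
    """Bounding box polygon of a rectangular mask (lon/lat degrees)."""
    rows, cols = np.nonzero(mask)
    cs = raster.cellsize
    west = raster.xll + cols.min() * cs
    east = raster.xll + (cols.max() + 1) * cs
    north = raster.ytop - rows.min() * cs
    south = raster.ytop - (rows.max() + 1) * cs
    return box(west, south, east, north)


def write_world(
    out_dir: str | Path,
    seed: int,
    *,
    rows: int = DEFAULT_ROWS,
    cols: int = DEFAULT_COLS,
    smoothness: float = DEFAULT_SMOOTHNESS,
    intensity: float = DEFAULT_INTENSITY,
    detect_prob: float = DEFAULT_DETECT_PROB,
    true_rho: float = 0.5,
    params: SpeciesParams | None = None,
) -> dict[str, Path]:
    """Generate and write a complete synthetic world.

    Writes ``habitat.asc``, ``detections.csv``, ``benchmark.geojson`` and
    ``truth.json`` (the last is a test-only oracle, never read by the
    pipeline).  Returns the file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raster = gen_habitat(seed, rows, cols, smoothness)
    truth = gen_groups(raster, params, intensity, seed + 1, true_rho=true_rho)
    records = gen_detections(truth, detect_prob, seed + 2)
    win = min(70, rows // 2, cols // 2)
    mask = benchmark_mask(raster, rows=win, cols=win)
    paths = {
        "habitat": out_dir / "habitat.asc",
        "detections": out_dir / "detections.csv",
        "benchmark": out_dir / "benchmark.geojson",
        "truth": out_dir / "truth.json",
    }
    write_asc(raster, paths["habitat"])
    write_detections(records, paths["detections"])
    write_region_geojson(mask_to_polygon(raster, mask), paths["benchmark"])
    truth.to_json(paths["truth"])
    return paths
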