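"""Habitat-preference/population curves and regional extrapolation.

Per habitat bin, the calibrated per-spot abundance values are turned into a
continuous curve by a two-threshold smoothing tensor: a mean filter of
half-width ``t1`` over the bin axis, a univariate smoothing spline over the
supported bins evaluated at all 685 bins (clipped at zero), then a second
mean filter of half-width ``t2``.  Every (t1, t2) pair yields its own curve;
the bin-wise mean over all pairs is the final habitat-preference/population
curve, and the dispersion of region totals across pairs quantifies the
smoothing uncertainty reported as the ``±`` spread.

A region's upper-limit abundance is the sum over bins of its pixel count
times the curve value (expected individuals per 1.143 km² pixel spot).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import UnivariateSpline

from .calibration import SpotSummary, mean_filter
from .errors import ValidationError
from .raster import N_BINS, HabitatHistogram

log = logging.getLogger(__name__)

__all__ = [
    "AbundanceCurve",
    "CurveTensor",
    "RegionEstimate",
    "FULL_THRESHOLDS",
    "spot_population",
    "spot_populations",
    "build_curve_tensor",
    "mean_curve",
    "estimate_region",
    "region_totals",
    "group_density",
    "report",
]

#: Threshold grid of the full-resolution tensor: 684 thresholds per axis,
#: giving 684² = 467,856 curve entries.
FULL_THRESHOLDS: tuple[int, ...] = tuple(range(N_BINS - 1))


@dataclass
class AbundanceCurve:
    """Expected individuals per spot as a function of habitat bin."""

    values: np.ndarray
    rho_tag: str = "best"
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_BINS,):
            raise ValidationError(f"curve must have {N_BINS} bins")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError("curve values must be finite and nonnegative")

    def mean_per_spot(self) -> float:
        """Average of the curve over all habitat bins (individuals/spot)."""
        return float(self.values.mean())


def spot_population(summary: SpotSummary, parametric: np.ndarray, bin_index: int) -> float:
    """Population term of one habitat bin:
    ``mean_expected[h] * spots_count[h] * parametric[h]``."""
    if summary.spots_count[bin_index] == 0:
        return 0.0
    v = summary.mean_expected[bin_index] * summary.spots_count[bin_index] * parametric[bin_index]
    if not np.isfinite(v):
        log.warning("spot_population: bin %d unsupported (zero raw diffusion)", bin_index)
        return float("nan")
    return float(v)


def spot_populations(summary: SpotSummary, parametric: np.ndarray) -> np.ndarray:
    """Vector of per-bin population terms; NaN marks unsupported data bins,
    0 marks bins without data spots."""
    out = np.zeros(N_BINS)
    data = summary.data_bins
    out[data] = summary.mean_expected[data] * summary.spots_count[data] * parametric[data]
    return out


@dataclass
class CurveTensor:
    """Grid of smoothed curves indexed by (pre-spline, post-spline)
    mean-filter thresholds.

    Only the ``t1`` (post-spline-free) stage is materialized; each entry
    ``(t1_i, t2_j)`` is generated on demand by filtering the splined curve,
    so the full 684² grid never needs 684² × 685 floats at once.
    """

    t1_grid: tuple[int, ...]
    t2_grid: tuple[int, ...]
    splined: np.ndarray  # (len(t1_grid), N_BINS), clipped at 0

    @property
    def n_entries(self) -> int:
        return len(self.t1_grid) * len(self.t2_grid)

    def entry(self, i: int, j: int) -> np.ndarray:
        return mean_filter(self.splined[i], self.t2_grid[j])

    def blocks(self) -> Iterable[np.ndarray]:
        """Yield per-t1 blocks of shape (len(t2_grid), N_BINS)."""
        for i in range(len(self.t1_grid)):
            yield np.stack([self.entry(i, j) for j in range(len(self.t2_grid))])

    def axis_weights(self, axis: int = 0) -> np.ndarray:
        """Quadrature weight of each grid point under the uniform measure
        over the full threshold range.

        A subsampled grid must estimate the plain average of the *full*
        tensor; each point is therefore weighted by the share of thresholds
        it represents (midpoint rule).  At full resolution the weights are
        exactly uniform.
        """
        t = np.asarray(self.t1_grid if axis == 0 else self.t2_grid, dtype=float)
        if t.size == 1:
            return np.ones(1)
        mid = np.concatenate(([t[0] - 0.5], (t[:-1] + t[1:]) / 2.0, [t[-1] + 0.5]))
        w = np.diff(mid)
        return w / w.sum()

    def entry_weights(self) -> np.ndarray:
        """Weight matrix over (t1, t2) entries, summing to 1."""
        return np.outer(self.axis_weights(0), self.axis_weights(1))


def _fit_spline(x: np.ndarray, y: np.ndarray, smoothing: float | None) -> np.ndarray:
    """Cubic smoothing spline through (x, y), evaluated at all bins.

    Degree drops 3 → 2 → 1 when fewer than 4/3 points are supported; a single
    point yields a constant curve.
    """
    m = x.size
    grid = np.arange(N_BINS, dtype=float)
    if m == 1:
        return np.full(N_BINS, y[0])
    k = min(3, m - 1)
    if k < 3:
        log.warning("spline degree reduced to %d (%d supported bins)", k, m)
    s = float(m) if smoothing is None else float(smoothing)
    # the smoothing budget applies to rms-normalized values so the fit is
    # scale-equivariant (doubling the anchor doubles the curve exactly)
    scale = float(np.sqrt(np.mean(y**2)))
    if scale == 0.0:
        return np.zeros(N_BINS)
    # ext=3: hold the boundary value outside the supported bin range; the
    # spline interpolates between data, it must not extrapolate polynomially.
    # fitpack may hit its iteration cap hunting for a tight smoothing target;
    # the returned approximation is acceptable, so silence that warning.
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*maximal number of iterations.*")
        spl = UnivariateSpline(x.astype(float), (y / scale).astype(float), k=k, s=s, ext=3)
    return scale * spl(grid)


def build_curve_tensor(
    bin_values: np.ndarray,
    thresholds_t1: Sequence[int],
    thresholds_t2: Sequence[int],
    *,
    smoothing: float | None = None,
) -> CurveTensor:
    """Build the smoothing tensor from per-bin values.

    ``bin_values`` holds the per-spot population value at bins with data and
    NaN elsewhere (unsupported data bins are also NaN and are skipped with
    the no-data bins).  For each ``t1``: bins without data contribute zeros
    to the mean filter, the spline is fitted over the bins whose window
    touches at least one data bin (smoothing parameter defaults to that
    count), and negative spline excursions are clipped to zero.
    """
    bin_values = np.asarray(bin_values, dtype=float)
    if bin_values.shape != (N_BINS,):
        raise ValidationError(f"bin_values must have length {N_BINS}")
    has_data = np.isfinite(bin_values)
    if not has_data.any():
        raise ValidationError("no supported habitat bins to build a curve from")
    filled = np.where(has_data, bin_values, 0.0)
    t1_grid = tuple(int(t) for t in thresholds_t1)
    t2_grid = tuple(int(t) for t in thresholds_t2)
    splined = np.empty((len(t1_grid), N_BINS))
    for i, t1 in enumerate(t1_grid):
        F = mean_filter(filled, t1)
        touched = mean_filter(has_data.astype(float), t1) > 0
        x = np.nonzero(touched)[0]
        curve = _fit_spline(x, F[x], smoothing)
        splined[i] = np.clip(curve, 0.0, None)
    return CurveTensor(t1_grid=t1_grid, t2_grid=t2_grid, splined=splined)


def mean_curve(tensor: CurveTensor, rho_tag: str = "best") -> AbundanceCurve:
    """Bin-wise average over the tensor entries, with bin-wise SD attached.

    Entries are weighted by the share of the full threshold range each grid
    point represents, so a subsampled tensor estimates the full-resolution
    tensor's plain mean (at full resolution this is the plain mean).
    """
    w1 = tensor.axis_weights(0)
    w2 = tensor.axis_weights(1)
    total = np.zeros(N_BINS)
    total_sq = np.zeros(N_BINS)
    for i, block in enumerate(tensor.blocks()):
        wb = (w1[i] * w2)[:, None]
        total += (wb * block).sum(axis=0)
        total_sq += (wb * block**2).sum(axis=0)
    var = np.maximum(total_sq - total**2, 0.0)
    return AbundanceCurve(values=total, rho_tag=rho_tag, sd=np.sqrt(var))


def estimate_region(curve: AbundanceCurve, hist: HabitatHistogram) -> float:
    """Region abundance: sum over bins of pixel count × curve value."""
    return float(np.asarray(hist.counts, dtype=float) @ curve.values)


def region_totals(tensor: CurveTensor, hist: HabitatHistogram) -> np.ndarray:
    """Region abundance under every tensor entry, shape (T1, T2)."""
    counts = np.asarray(hist.counts, dtype=float)
    return np.stack([block @ counts for block in tensor.blocks()])


def group_density(curve_mean_per_spot: float, spot_area_km2: float = 1.143) -> float:
    """Convert a curve average (individuals/spot) to groups/km²."""
    if spot_area_km2 <= 0:
        raise ValidationError(f"spot area must be > 0, got {spot_area_km2}")
    return curve_mean_per_spot / spot_area_km2


@dataclass
class RegionEstimate:
    """Lower/best/upper abundance for one region, with the smoothing spread
    (SD of the best-bound region total across tensor entries)."""

    region_tag: str
    lower: float
    best: float
    upper: float
    spread: float = 0.0
    group: str | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            # the per-bound anchors normally order the estimates; report the
            # inversion rather than hiding it
            log.warning("%s: lower estimate %.6g exceeds upper %.6g",
                        self.region_tag, self.lower, self.upper)
        if self.spread < 0:
            raise ValidationError(f"{self.region_tag}: spread must be >= 0")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def report(regions: Sequence[RegionEstimate], out_path: str | Path) -> dict:
    """Write the regional estimates as CSV and JSON.

    Rows are sorted by region tag; per-group aggregate rows and an overall
    total are exact sums of their members (rounded to integers only at
    output).  Returns the JSON document.
    """
    if not regions:
        raise ValidationError("no region estimates to report")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    rows = sorted(regions, key=lambda r: r.region_tag)

    def agg(tag: str, members: Sequence[RegionEstimate]) -> RegionEstimate:
        return RegionEstimate(
            region_tag=tag,
            lower=sum(r.lower for r in members),
            best=sum(r.best for r in members),
            upper=sum(r.upper for r in members),
            spread=sum(r.spread for r in members),
        )

    groups = sorted({r.group for r in rows if r.group is not None})
    out_rows: list[tuple[str, RegionEstimate]] = [("region", r) for r in rows]
    for gname in groups:
        out_rows.append(("aggregate", agg(gname, [r for r in rows if r.group == gname])))
    out_rows.append(("aggregate", agg("total", rows)))

    doc = {
        "regions": [
            {
                "tag": r.region_tag,
                "kind": kind,
                "lower": _round_half_up(r.lower),
                "best": _round_half_up(r.best),
                "upper": _round_half_up(r.upper),
                "spread": _round_half_up(r.spread),
                "lower_exact": r.lower,
                "best_exact": r.best,
                "upper_exact": r.upper,
            }
            for kind, r in out_rows
        ]
    }
    json_path = out_path.with_suffix(".json")
    csv_path = out_path.with_suffix(".csv")
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=2)
    with open(csv_path, "w") as fh:
        fh.write("region,kind,lower,best,upper,spread\n")
        for row in doc["regions"]:
            fh.write(
                f"{row['tag']},{row['kind']},{row['lower']},{row['best']},"
                f"{row['upper']},{row['spread']}\n"
            )
    return doc
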