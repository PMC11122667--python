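"""Diffusion correction over habitat bins and benchmark calibration.

Locations where a species was never reported are not absences in
presence-only data (the *null result penalty*).  The correction used here is
a *diffusion* factor per habitat bin: the (mean-filtered) number of map
pixels sharing that habitat preference.  Dividing per-bin observed abundance
by the diffusion factor converts it into a per-pixel expectation that treats
unreported pixels of the same preference as zeros.

The raw diffusion is rescaled ("parametric diffusion") so that the benchmark
region — an area with an independently reported population — is reproduced
exactly by the unsmoothed prediction.  The inquisitiveness ``rho`` is then
optimized so the final smoothed-curve estimate over the benchmark matches the
reported population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import CalibrationError, ValidationError
from .group_size import ExpectationCurve
from .raster import N_BINS, HabitatHistogram

log = logging.getLogger(__name__)

__all__ = [
    "BenchmarkRegion",
    "SpotSummary",
    "CalibrationScale",
    "CalibrationResult",
    "raw_diffusion",
    "diffusion_table",
    "spot_summary",
    "benchmark_factor",
    "parametric_diffusion",
    "calibrate_rho",
]


@dataclass
class BenchmarkRegion:
    """Region with an independently reported population range."""

    mask: np.ndarray
    reported_lower: float
    reported_best: float
    reported_upper: float
    region_tag: str = "benchmark"

    def __post_init__(self) -> None:
        if not (0 < self.reported_lower <= self.reported_best <= self.reported_upper):
            raise ValidationError(
                "need 0 < lower <= best <= upper, got "
                f"({self.reported_lower}, {self.reported_best}, {self.reported_upper})"
            )
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValidationError("benchmark mask is empty")


@dataclass
class SpotSummary:
    """Per habitat bin: number of data spots and their mean expected
    individuals ``E_N(s)``.  Full-length (685) arrays; bins with no spots
    have count 0 and NaN mean."""

    spots_count: np.ndarray
    mean_expected: np.ndarray

    def __post_init__(self) -> None:
        if self.spots_count.shape != (N_BINS,) or self.mean_expected.shape != (N_BINS,):
            raise ValidationError(f"summary arrays must have length {N_BINS}")

    @property
    def data_bins(self) -> np.ndarray:
        return np.nonzero(self.spots_count > 0)[0]


@dataclass(frozen=True)
class CalibrationScale:
    """Benchmark scaling factor at a given rho and filter threshold."""

    factor: float
    rho: float
    threshold: int

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise CalibrationError(f"scaling factor must be > 0, got {self.factor}")


def raw_diffusion(hist: HabitatHistogram, t: int) -> np.ndarray:
    """Mean-filtered pixel counts per habitat bin.

    ``raw[h]`` is the mean of the histogram over bins ``h-t .. h+t``, with
    the window truncated at the scale boundaries (the divisor is the number
    of in-range bins).  ``t = 0`` is the identity; ``t = 684`` yields the
    global mean in every bin.
    """
    if not (0 <= t <= N_BINS - 1):
        raise ValidationError(f"threshold must be in [0, {N_BINS - 1}], got {t}")
    c = np.asarray(hist.counts, dtype=float)
    cs = np.concatenate(([0.0], np.cumsum(c)))
    h = np.arange(N_BINS)
    lo = np.maximum(h - t, 0)
    hi = np.minimum(h + t, N_BINS - 1)
    return (cs[hi + 1] - cs[lo]) / (hi - lo + 1)


def mean_filter(values: np.ndarray, t: int) -> np.ndarray:
    """Truncated-window mean filter over the habitat-bin axis (last axis)."""
    v = np.asarray(values, dtype=float)
    n = v.shape[-1]
    cs = np.concatenate((np.zeros(v.shape[:-1] + (1,)), np.cumsum(v, axis=-1)), axis=-1)
    h = np.arange(n)
    lo = np.maximum(h - t, 0)
    hi = np.minimum(h + t, n - 1)
    return (cs[..., hi + 1] - cs[..., lo]) / (hi - lo + 1)


def diffusion_table(hist: HabitatHistogram, thresholds: Sequence[int]) -> np.ndarray:
    """Matrix ``raw[h, j]`` of raw diffusion at each threshold ``thresholds[j]``."""
    return np.column_stack([raw_diffusion(hist, int(t)) for t in thresholds])


def spot_summary(spots, curve: ExpectationCurve) -> SpotSummary:
    """Group spots by habitat bin; per bin, count spots and average
    ``E_N(signals)`` over them."""
    spots = [sp for sp in spots if sp.habitat_bin is not None]
    if not spots:
        raise ValidationError("no spots with habitat bins; run assign_bins first")
    bins = np.array([sp.habitat_bin for sp in spots])
    signals = np.array([sp.signals for sp in spots])
    expected = curve(signals)
    counts = np.bincount(bins, minlength=N_BINS).astype(float)
    sums = np.bincount(bins, weights=expected, minlength=N_BINS)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return SpotSummary(spots_count=counts, mean_expected=means)


def benchmark_factor(
    summary: SpotSummary,
    raw: np.ndarray,
    reported: float,
    *,
    rho: float,
    threshold: int,
) -> CalibrationScale:
    """Benchmark scaling factor.

    ``factor = reported / sum_h mean_expected[h] * spots_count[h] / raw[h]``
    over bins with data; the denominator is the benchmark abundance predicted
    from raw diffusion alone.  Data bins where the raw diffusion is zero are
    excluded with a warning; if none remain the calibration fails.
    """
    if reported <= 0:
        raise CalibrationError(f"reported population must be > 0, got {reported}")
    data = summary.data_bins
    if data.size == 0:
        raise CalibrationError("no habitat bins contain data spots")
    supported = data[raw[data] > 0]
    dropped = sorted(set(data) - set(supported))
    if dropped:
        log.warning("benchmark_factor: %d bins with zero raw diffusion excluded: %s",
                    len(dropped), dropped)
    if supported.size == 0:
        raise CalibrationError(f"zero raw diffusion at every data bin: {sorted(data)}")
    denom = float(
        np.sum(summary.mean_expected[supported] * summary.spots_count[supported] / raw[supported])
    )
    if denom <= 0:
        raise CalibrationError(f"non-positive raw-diffusion prediction at bins {sorted(data)}")
    return CalibrationScale(factor=reported / denom, rho=rho, threshold=threshold)


def parametric_diffusion(raw: np.ndarray, scale: CalibrationScale) -> np.ndarray:
    """Per-bin parametric diffusion ``factor / raw[h]``.

    Bins with zero raw diffusion are unsupported and returned as NaN; they
    are excluded downstream.
    """
    out = np.full(raw.shape, np.nan)
    ok = raw > 0
    out[ok] = scale.factor / raw[ok]
    n_bad = int((~ok).sum())
    if n_bad:
        log.debug("parametric_diffusion: %d unsupported bins (zero raw diffusion)", n_bad)
    return out


@dataclass
class CalibrationResult:
    """Outcome of the rho optimization against a benchmark target."""

    rho: float
    attained: bool
    residual: float
    n_evaluations: int
    message: str
    evaluations: list[tuple[float, float]] = field(default_factory=list)


def calibrate_rho(
    estimate_fn: Callable[[float], float],
    target: float,
    *,
    grid: int = 11,
    rel_tol: float = 1e-4,
    max_iter: int = 60,
) -> CalibrationResult:
    """Find ``rho`` in [0, 1] whose benchmark estimate matches ``target``.

    A coarse grid locates a sign change of ``g(rho) = estimate/target - 1``;
    bisection then refines it to the relative tolerance.  If no bracket
    exists the grid minimizer of ``|g|`` is returned with a diagnostic (for a
    monotone ``g`` this is the closest endpoint).
    """
    if target <= 0:
        raise CalibrationError(f"target population must be > 0, got {target}")
    rhos = np.linspace(0.0, 1.0, grid)
    evals: list[tuple[float, float]] = []

    def g(rho: float) -> float:
        val = estimate_fn(float(rho)) / target - 1.0
        evals.append((float(rho), val))
        return val

    gv = np.array([g(r) for r in rhos])
    if np.any(np.abs(gv) <= rel_tol):
        i = int(np.argmin(np.abs(gv)))
        return CalibrationResult(float(rhos[i]), True, float(gv[i]), len(evals),
                                 "target matched on coarse grid", evals)
    sign_change = np.nonzero(np.sign(gv[:-1]) * np.sign(gv[1:]) < 0)[0]
    if sign_change.size == 0:
        i = int(np.argmin(np.abs(gv)))
        msg = ("target outside attainable range; returning "
               + ("endpoint" if i in (0, grid - 1) else "grid minimizer (non-monotone estimate)"))
        log.warning("calibrate_rho: %s (residual %.4g)", msg, gv[i])
        return CalibrationResult(float(rhos[i]), False, float(gv[i]), len(evals), msg, evals)
    # prefer the bracket with the smallest endpoint residual
    j = int(sign_change[np.argmin(np.minimum(np.abs(gv[sign_change]), np.abs(gv[sign_change + 1])))])
    lo, hi = float(rhos[j]), float(rhos[j + 1])
    glo = gv[j]
    best_rho, best_g = (lo, glo) if abs(glo) < abs(gv[j + 1]) else (hi, gv[j + 1])
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        gm = g(mid)
        if abs(gm) < abs(best_g):
            best_rho, best_g = mid, gm
        if abs(gm) <= rel_tol:
            return CalibrationResult(mid, True, gm, len(evals), "bisection converged", evals)
        if np.sign(gm) == np.sign(glo):
            lo, glo = mid, gm
        else:
            hi = mid
    attained = abs(best_g) <= rel_tol
    return CalibrationResult(best_rho, attained, best_g, len(evals),
                             "bisection exhausted iterations", evals)
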