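"""Semiempirical conditional group-size model.

Given the number of GPS signals ``s`` observed at a fixed-area spot, the model
assigns a probability to every admissible group size ``n`` in
``[n_min, n_max]``::

    P{N = n | S = s}  ∝  base(n) · n^sigma,       sigma = s^(1 - rho)

``base(n)`` is a two-component log-normal group-size law separating
nonprovisioned from provisioned (human-subsidized) groups, and ``rho`` — the
species' *inquisitiveness* — discounts double counting: at ``rho = 0`` every
signal is a distinct individual (``sigma = s``), at ``rho = 1`` all signals
are repeats of one individual (``sigma = 1``).

The conditional expectation ``E_N(s)`` of this distribution is the expected
number of individuals at a spot with ``s`` signals; it is the quantity the
downstream calibration and extrapolation stages consume.

Two readings of the two-component base law are provided:

``"geometric"`` (default)
    log-linear pooling ``LN1(n)^(1-ProvRt) · LN2(n)^(ProvRt)``.
``"arithmetic"``
    the ordinary mixture ``(1-ProvRt)·LN1(n) + ProvRt·LN2(n)``.

The geometric form is the default because it tracks the published regime
behavior of the model far more closely (a gradual dominance switch between the
nonprovisioned and provisioned components as ``s`` grows, and an expectation
curve that plateaus near the provisioned mean before the terminal
concentration at ``n_max``).  The arithmetic form is the natural sampling law
for a population in which a fraction ``ProvRt`` of groups is provisioned and
is what the synthetic generator draws from; the switch lets the two be
compared directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import logsumexp

from .errors import InvalidParameterError

__all__ = [
    "SpeciesParams",
    "LogNormalShape",
    "ConditionalDistribution",
    "ExpectationCurve",
    "NO_CROSSOVER",
    "MixtureForm",
    "lognormal_shape",
    "base_density",
    "adjusted_signals",
    "ways_count",
    "conditional_distribution",
    "expected_group_size",
    "expectation_curve",
    "crossover_signal",
]

MixtureForm = Literal["geometric", "arithmetic"]

#: Sentinel returned by :func:`crossover_signal` when the provisioned
#: component never dominates within the scanned signal range.
NO_CROSSOVER: int = -1


@dataclass(frozen=True)
class SpeciesParams:
    """Species-specific inputs of the group-size model.

    Defaults are the long-tailed macaque values: groups of 5-200 individuals,
    2.5% of groups provisioned, nonprovisioned mean 20 (SD 15), provisioned
    mean 170 (SD 30).
    """

    n_min: int = 5
    n_max: int = 200
    prov_ratio: float = 0.025
    mean_nonprov: float = 20.0
    mean_prov: float = 170.0
    sd_nonprov: float = 15.0
    sd_prov: float = 30.0

    def __post_init__(self) -> None:
        if not (1 <= self.n_min < self.n_max):
            raise InvalidParameterError(
                f"need 1 <= n_min < n_max, got ({self.n_min}, {self.n_max})"
            )
        if not (0.0 < self.prov_ratio < 1.0):
            raise InvalidParameterError(f"prov_ratio must be in (0,1), got {self.prov_ratio}")
        for name in ("mean_nonprov", "mean_prov"):
            v = getattr(self, name)
            if not (self.n_min <= v <= self.n_max):
                raise InvalidParameterError(f"{name}={v} outside [{self.n_min}, {self.n_max}]")
        for name in ("sd_nonprov", "sd_prov"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    @property
    def support(self) -> np.ndarray:
        """Integer group sizes ``n_min .. n_max`` (inclusive)."""
        return np.arange(self.n_min, self.n_max + 1)


@dataclass(frozen=True)
class LogNormalShape:
    """Log-scale location ``M`` and scale ``Z`` of a log-normal component."""

    location: float
    scale: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.location) and math.isfinite(self.scale)):
            raise InvalidParameterError("log-normal shape must be finite")
        if self.scale <= 0:
            raise InvalidParameterError(f"scale must be > 0, got {self.scale}")


def lognormal_shape(mean: float, sd: float) -> LogNormalShape:
    """Moment-matched log-normal shape for a given arithmetic mean and SD.

    Uses the standard identities ``Z^2 = ln(1 + (sd/mean)^2)`` and
    ``M = ln(mean^2 / sqrt(mean^2 + sd^2))``, so that a log-normal with these
    shape parameters has exactly the requested arithmetic mean and SD.
    """
    if mean <= 0 or sd <= 0:
        raise InvalidParameterError(f"mean and sd must be > 0, got ({mean}, {sd})")
    z2 = math.log1p((sd / mean) ** 2)
    return LogNormalShape(
        location=math.log(mean**2 / math.sqrt(mean**2 + sd**2)),
        scale=math.sqrt(z2),
    )


def _log_pdf(n: np.ndarray, shape: LogNormalShape) -> np.ndarray:
    """Log of the log-normal density evaluated at integer sizes ``n``."""
    ln_n = np.log(n)
    return (
        -np.log(n * shape.scale * math.sqrt(2.0 * math.pi))
        - (ln_n - shape.location) ** 2 / (2.0 * shape.scale**2)
    )


def _log_components(params: SpeciesParams) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted component log-densities (nonprovisioned, provisioned)."""
    n = params.support.astype(float)
    l1 = _log_pdf(n, lognormal_shape(params.mean_nonprov, params.sd_nonprov))
    l2 = _log_pdf(n, lognormal_shape(params.mean_prov, params.sd_prov))
    return l1, l2


def _log_base(params: SpeciesParams, mixture: MixtureForm) -> np.ndarray:
    l1, l2 = _log_components(params)
    w = params.prov_ratio
    if mixture == "geometric":
        return (1.0 - w) * l1 + w * l2
    if mixture == "arithmetic":
        return np.logaddexp(math.log1p(-w) + l1, math.log(w) + l2)
    raise InvalidParameterError(f"unknown mixture form {mixture!r}")


def base_density(params: SpeciesParams, mixture: MixtureForm = "geometric") -> np.ndarray:
    """Normalized base group-size weights over the integer support.

    The log-normal densities are used as unnormalized weights at the integer
    sizes and normalized by summation; no bin integration is performed.
    """
    lb = _log_base(params, mixture)
    w = np.exp(lb - lb.max())
    return w / w.sum()


def adjusted_signals(s: int, rho: float) -> float:
    """Signal count adjusted for double counting: ``sigma = s^(1-rho)``.

    ``rho = 0`` keeps every signal (``sigma = s``); ``rho = 1`` collapses all
    signals to one individual (``sigma = 1``).
    """
    if s < 1:
        raise InvalidParameterError(f"signal count must be >= 1, got {s}")
    if not (0.0 <= rho <= 1.0):
        raise InvalidParameterError(f"rho must be in [0,1], got {rho}")
    return float(s) ** (1.0 - rho)


def ways_count(n: int, s: int) -> int:
    """Number of ways ``n`` equally detectable individuals generate ``s``
    signals: ``n^s``, in exact integer arithmetic."""
    if n < 1 or s < 0:
        raise InvalidParameterError(f"need n >= 1 and s >= 0, got ({n}, {s})")
    return int(n) ** int(s)


@dataclass(frozen=True)
class ConditionalDistribution:
    """``P{N = n | S = s}`` over the integer support ``n_min .. n_max``."""

    s: int
    rho: float
    support: np.ndarray
    probabilities: np.ndarray

    def expectation(self) -> float:
        return float(self.support @ self.probabilities)

    def prob(self, n: int) -> float:
        lo = int(self.support[0])
        if not lo <= n <= int(self.support[-1]):
            return 0.0
        return float(self.probabilities[n - lo])


def _log_weights(sigma: float, log_base: np.ndarray, support: np.ndarray) -> np.ndarray:
    return log_base + sigma * np.log(support.astype(float))


def conditional_distribution(
    s: int,
    rho: float,
    params: SpeciesParams,
    *,
    mixture: MixtureForm = "geometric",
    base_weights: np.ndarray | None = None,
) -> ConditionalDistribution:
    """Conditional group-size distribution given ``s`` GPS signals.

    Probabilities are proportional to ``base(n) * n^sigma`` with
    ``sigma = adjusted_signals(s, rho)``.  All products are computed as sums
    of logarithms with a max-subtraction normalization, so ``n^sigma`` cannot
    overflow even for very large ``s``.

    ``base_weights`` optionally replaces the log-normal mixture with an
    explicit nonnegative weight vector over the support (uniform weights
    recover the pure counting model ``P ∝ n^sigma``).
    """
    sigma = adjusted_signals(s, rho)
    support = params.support
    if base_weights is None:
        lb = _log_base(params, mixture)
    else:
        base_weights = np.asarray(base_weights, dtype=float)
        if base_weights.shape != support.shape:
            raise InvalidParameterError(
                f"base_weights length {base_weights.size} != support {support.size}"
            )
        if np.any(base_weights < 0) or not np.any(base_weights > 0):
            raise InvalidParameterError("base_weights must be nonnegative with positive mass")
        with np.errstate(divide="ignore"):
            lb = np.log(base_weights)
    lw = _log_weights(sigma, lb, support)
    w = np.exp(lw - lw.max())
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ArithmeticError("non-finite weights in conditional distribution")
    return ConditionalDistribution(s=int(s), rho=float(rho), support=support, probabilities=w / total)


def expected_group_size(
    s: int,
    rho: float,
    params: SpeciesParams,
    *,
    mixture: MixtureForm = "geometric",
    base_weights: np.ndarray | None = None,
) -> float:
    """Conditional expectation ``E_N(s) = <N | S = s>`` (individuals)."""
    return conditional_distribution(
        s, rho, params, mixture=mixture, base_weights=base_weights
    ).expectation()


@dataclass
class ExpectationCurve:
    """Vectorized, cached map ``s -> E_N(s)`` at fixed ``rho``.

    ``values(s)`` accepts scalars or integer arrays; results are cached per
    distinct ``s`` so pipelines that revisit the same signal counts pay for
    each count once.
    """

    rho: float
    params: SpeciesParams = field(default_factory=SpeciesParams)
    mixture: MixtureForm = "geometric"
    _cache: dict[int, float] = field(default_factory=dict, repr=False)

    def __call__(self, s):
        arr = np.atleast_1d(np.asarray(s))
        out = np.empty(arr.shape, dtype=float)
        lb = _log_base(self.params, self.mixture)
        support = self.params.support
        ln_n = np.log(support.astype(float))
        for idx, si in np.ndenumerate(arr):
            si = int(si)
            if si not in self._cache:
                sigma = adjusted_signals(si, self.rho)
                lw = lb + sigma * ln_n
                w = np.exp(lw - lw.max())
                self._cache[si] = float((support * w).sum() / w.sum())
            out[idx] = self._cache[si]
        if np.ndim(s) == 0:
            return float(out[0])
        return out


def expectation_curve(
    rho: float,
    params: SpeciesParams | None = None,
    mixture: MixtureForm = "geometric",
) -> ExpectationCurve:
    """Build the conditional-expectation curve ``E_N`` at a given ``rho``."""
    return ExpectationCurve(rho=float(rho), params=params or SpeciesParams(), mixture=mixture)


def _component_log_masses(
    sigmas: np.ndarray, params: SpeciesParams, mixture: MixtureForm
) -> tuple[np.ndarray, np.ndarray]:
    """Log of (nonprovisioned, provisioned) probability mass for each sigma.

    Mass is attributed by the two-component decomposition: for the arithmetic
    mixture the components are its additive terms; for geometric pooling each
    size ``n`` carries the responsibility of the prov-ratio-weighted component
    densities at ``n``.
    """
    support = params.support.astype(float)
    ln_n = np.log(support)
    l1, l2 = _log_components(params)
    w = params.prov_ratio
    a1 = math.log1p(-w) + l1
    a2 = math.log(w) + l2
    tilt = sigmas[:, None] * ln_n[None, :]
    if mixture == "arithmetic":
        m1 = logsumexp(a1[None, :] + tilt, axis=1)
        m2 = logsumexp(a2[None, :] + tilt, axis=1)
    else:
        base = ((1.0 - w) * l1 + w * l2)[None, :] + tilt
        denom = np.logaddexp(a1, a2)
        m1 = logsumexp(base + (a1 - denom)[None, :], axis=1)
        m2 = logsumexp(base + (a2 - denom)[None, :], axis=1)
    return m1, m2


def crossover_signal(
    rho: float,
    params: SpeciesParams,
    *,
    mixture: MixtureForm = "geometric",
    s_max: int = 10**6,
    chunk: int = 8192,
) -> int:
    """Smallest ``s`` at which the provisioned component's conditional mass
    strictly exceeds the nonprovisioned component's.

    Scans ``s`` upward from 1; returns :data:`NO_CROSSOVER` if dominance never
    happens for ``s <= s_max``.  At ``rho = 1`` the distribution is the same
    for every ``s``, so the answer is decided at ``s = 1``.
    """
    if not (0.0 <= rho <= 1.0):
        raise InvalidParameterError(f"rho must be in [0,1], got {rho}")
    if rho == 1.0:
        m1, m2 = _component_log_masses(np.array([1.0]), params, mixture)
        return 1 if m2[0] > m1[0] else NO_CROSSOVER
    s = 1
    while s <= s_max:
        hi = min(s + chunk, s_max + 1)
        ss = np.arange(s, hi, dtype=float)
        sigmas = ss ** (1.0 - rho)
        m1, m2 = _component_log_masses(sigmas, params, mixture)
        dom = np.nonzero(m2 > m1)[0]
        if dom.size:
            return int(ss[dom[0]])
        s = hi
    return NO_CROSSOVER
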