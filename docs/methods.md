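# Methods

This note documents the model implemented by `habpop`, the choices made
where the method's published description is ambiguous or silent, what the
synthetic-data generator does and does not emulate, and the known
limitations of the estimator. It is the companion to the test suite: every
behavioral claim here is exercised by a test or by `scripts/acceptance.py`.

## 1. Conditional group-size model

For a spot with `s` aggregated GPS signals, the group-size law is the
tilted two-component distribution

    P{N = n | S = s} ∝ base(n) · n^σ,   σ = s^(1−ρ),   n = N_min … N_max.

The tilt follows from a uniform-detectability argument: `n` individuals can
produce a given sequence of `σ` distinct-individual signals in `n^σ` ways.
`σ` discounts double counting: the inquisitiveness ρ interpolates between
"every signal is a new individual" (ρ = 0, σ = s) and "all signals repeat
one individual" (ρ = 1, σ = 1). We read the exponent as the power tower
`n^(s^(1−ρ))` — the definition of σ is unambiguous, whereas the printed
equation typography is not. A consequence worth noting: at ρ ≈ 0.52 the
tilt reaches the full concentration regime (P{N = N_max} > 1 − 10⁻⁶) only
for s ≳ 10⁷; at s = 10⁶ the probability is ≈ 0.972 (computed by the
acceptance script).

**Log-normal components.** Each component is parameterized by its
arithmetic mean and SD through the standard moment-matching identities
Z² = ln(1 + (sd/mean)²), M = ln(mean²/√(mean² + sd²)). (The published
formulas omit the square roots; as printed they do not yield densities with
the stated means, so the standard identities are used.) Densities are
evaluated at integer sizes and normalized by summation — the log-normal is
an unnormalized weight, not integrated over bins.

**Mixture form.** The published expression for the base density is a
product of two log-normal factors carrying a garbled provisioned-ratio
exponent, compatible with either (a) an arithmetic mixture
`(1−w)·LN₁ + w·LN₂` or (b) log-linear (geometric) pooling
`LN₁^(1−w) · LN₂^w`. Both are implemented (`mixture=` switch). The only
published constraint that discriminates them is the regime boundary at
which the provisioned component's conditional mass begins to dominate,
reported at s = 45 for ρ = 0.523813. Measured with the default species
parameters, the arithmetic mixture switches at s = 5 and the geometric
pooling at s = 27 (frozen as regression values in the tests); neither
reproduces 45, and no defensible variant we scanned (printed shape
formulas, plain products, peak-height or mass-split attributions) does.
The **geometric form is the default**: it is much closer to the published
regime, it matches the printed product structure, and its expectation
curve shows the published gradual rise with a plateau near the provisioned
mean. The discrepancy with the published 45 is accepted and surfaced by
the acceptance suite rather than hidden.

**Component attribution.** For the crossover scan, conditional mass is
attributed to components by the prov-ratio-weighted responsibilities
`w·LN₂ / ((1−w)·LN₁ + w·LN₂)` evaluated per size (for the arithmetic
mixture these are its exact posterior component probabilities). The scan
proceeds upward from s = 1 with strict-inequality dominance; at ρ = 1 the
distribution is s-invariant and the scan reduces to s = 1.

**Numerics.** All products are sums of logarithms with max-subtraction
before exponentiation; `n^σ` therefore cannot overflow at any s. The
counting helper `ways_count` uses exact big-integer arithmetic.

## 2. Input parameters

| parameter | meaning | unit | default |
| --- | --- | --- | --- |
| N_min, N_max | group-size bounds | individuals | 5, 200 |
| ProvRt | fraction of provisioned groups | – | 0.025 |
| N_mean¹, σ_sd¹ | nonprovisioned mean, SD | individuals | 20, 15 |
| N_mean², σ_sd² | provisioned mean, SD | individuals | 170, 30 |
| ρ | inquisitiveness | – | calibrated in [0, 1] |
| grouping radius | home-range merge distance | m | 800 (= √(2/π) km) |
| cell size | spot grid pitch | degrees | 0.0131 |
| spot area | fixed area per cell | km² | 1.143 |
| habitat bins | quantization levels of h | – | 685 (indices 0–684) |

The defaults are the long-tailed macaque values. The spot area is a model
constant applied to every cell rather than recomputed per latitude (the
published side lengths are geodetically inconsistent, so the printed area
is adopted verbatim). Habitat preference is quantized to the nearest of
685 equispaced levels: `bin = floor(684·h + 0.5)`.

## 3. Detections to spots

Records (longitude, latitude, reported count ≥ 1, source) are grouped by
single-linkage clustering under the strict 800 m great-circle criterion —
the simplest rule satisfying the stated pairwise grouping; the pair search
uses a k-d tree on unit-sphere coordinates (chord length is monotone in
great-circle distance) with haversine verification, so strictness is exact
on a spherical Earth (R = 6371.0088 km). Cluster centroids are
count-weighted coordinate means. Clusters are then assigned to half-open
0.0131° grid cells aligned with the habitat raster's origin (edge points
belong to the higher-index cell), merging clusters that share a cell. A
spot's signal count is the **sum of reported individual counts** of its
member records, per the definition of s as the reported number of
individuals. Spots outside the raster or on no-data cells are dropped with
a warning, never imputed.

## 4. Diffusion correction and benchmark anchoring

Presence-only data never report absences. The raw diffusion factor of bin
h at threshold t is the truncated-window mean of the benchmark region's
pixel histogram over bins h−t … h+t (t = 0 is the identity; t = 684 the
global mean). Dividing a bin's observed abundance by its diffusion factor
converts it to a per-pixel expectation in which unsampled pixels of the
same preference count as zeros.

For one bound (an anchor population `R` and a fixed ρ):

1. `E_N` values of the benchmark spots are averaged per bin
   (`mean_h`, with `spots_h` the per-bin spot count);
2. the scaling factor is `R / Σ_h mean_h · spots_h / raw_h` — the
   denominator is the benchmark abundance predicted from raw diffusion
   alone — and per-bin populations are
   `pop_h = mean_h · spots_h · factor / raw_h`
   (their sum over data bins returns `R` identically, at every t);
3. the curve points are the per-pixel-spot values `v_h = pop_h / raw_h`,
   rescaled so the pixel-weighted benchmark sum `Σ_h B_h · v_h` equals `R`
   exactly (`B_h` = benchmark pixels in bin h). At t = 0 this rescaling is
   the identity; at t > 0 it removes the filter-induced anchor bias. This
   per-pixel normalization is what gives the final curves their
   individuals-per-spot units and makes region totals scale with region
   area.

The default diffusion threshold is t = 34 (5% of the bin scale): enough to
stabilize 1/raw at sparsely pixelled bins without erasing the histogram's
shape. Data bins with zero raw diffusion are excluded with a logged count.

## 5. Smoothing tensor and curves

For each pre-spline threshold t₁: the per-spot values (zeros at bins
without data) are mean-filtered at half-width t₁; a cubic smoothing spline
is fitted over the bins whose filter window touches data and evaluated at
all 685 bins; negative excursions are clipped to zero. Each post-spline
threshold t₂ applies a second mean filter. Design choices:

* the spline smoothing budget defaults to the number of supported bins,
  applied to rms-normalized values so the fit is scale-equivariant
  (doubling the anchor doubles the curve exactly); `smoothing=0` gives
  exact interpolation;
* degree drops 3 → 2 → 1 below 4/3 supported bins; a single bin yields a
  constant curve;
* outside the supported range the spline holds its boundary value
  (polynomial extrapolation produced unbounded artifacts that a zero-clip
  cannot remove).

The full tensor spans 684 thresholds per axis (684² = 467,856 entries).
The final curve is the tensor average; reduced resolutions (default 100
per axis) use **quadratically spaced grids with midpoint quadrature
weights**, so the subsampled average estimates the full grid's plain mean
— the smoothed curves vary fastest at small t, and an evenly spaced,
equally weighted subsample overweights those entries badly. Region totals
under 20- and 40-point grids agree within 5% in the tests. The ± spread
reported per region is the weighted SD of the region total across tensor
entries — this package's definition of the smoothing uncertainty.

A region's estimate is `Σ_h counts_h · curve_h` over its own pixel
histogram. The three bounds run the pipeline at (ρ = 0, reported lower),
(calibrated ρ, reported best), (ρ = 1, reported upper).

## 6. Calibrating ρ

`calibrate_rho` seeks the ρ whose smoothed-curve benchmark estimate equals
the reported best population (relative tolerance 10⁻⁴): an 11-point grid
locates a sign change of the relative misfit, bisection (≤ 60 iterations)
refines it; with no sign change the grid minimizer of the absolute misfit
is returned — the closest endpoint when the misfit is monotone — flagged
`attained=False` with the residual. The scaling factor inside the searched
pipeline is anchored to the region's reported best value, independent of
the search target, which makes the search a fixed-point-consistent root
problem.

**Identifiability caveat (important).** By construction the pre-smoothing
benchmark prediction equals the anchor at every ρ; the calibration signal
is therefore entirely the smoothing-tensor distortion — the spline filling
habitat bins that carry benchmark pixels but no data spots, offset by the
mean filter's zero dilution. ρ moves this distortion only through the
shape of E_N across spots (tens of percent), while the distortion's
magnitude is governed by how much of the benchmark's pixel mass lies in
bins containing data spots. When coverage is high (a data-dense benchmark,
as in the method's original application where the residual at ρ = 0 was
about 8%), the misfit crosses zero and the calibration is well-posed. When
coverage is low the misfit can keep one sign across all of [0, 1] and the
reported ρ is a fallback, not an estimate — the calibration report says so
explicitly. A zero crossing, where it exists, reflects smoothing behavior
as much as the generating inquisitiveness, so ρ recovered from sparse data
should be interpreted with care. The end-to-end recovery study in the
acceptance suite quantifies this on synthetic worlds and currently fails
its targets on most seeds; the failure is reported, not masked.

## 7. Synthetic worlds

The generator emulates the three field inputs with fully known truth:

* **Habitat**: a Gaussian random field (kernel SD 10 cells) rescaled to
  span [0, 1] exactly, on a 200×200 grid of 0.0131° cells by default.
* **Groups**: an inhomogeneous Poisson process with intensity proportional
  to habitat preference (0.013 groups/km² at h = 1, ≈ 300 groups on the
  default map — per-spot signal counts then sit near the original study's
  scale); each group is provisioned with probability ProvRt and sized from
  the matching log-normal, rounded and clamped to [N_min, N_max] (the
  sampling law is the arithmetic two-component mixture, regardless of the
  analysis default).
* **Detections**: per group, distinct detected individuals
  d ~ Binomial(size, 0.2); the signal total inverts the double-counting
  correction, s = round(d^(1/(1−ρ*))), so σ(s) ≈ d and the model's
  central assumption is exactly satisfiable; at ρ* = 1 each detected
  individual contributes a geometric number of signals with mean 3.
  Records are jittered uniformly within 400 m of the group center (inside
  one 800 m cluster); groups with extreme signal totals are written as at
  most 32 records whose counts sum to s.
* **Benchmark**: the densest high-preference 70×70 window (stride-10
  scan), emulating a protected sanctuary sitting in good habitat.

Not emulated: animal movement, camera placement bias, temporal dynamics,
misidentification, and observer heterogeneity. Passing tests therefore
show the pipeline's internal consistency and its behavior when the
double-counting assumption holds exactly — not robustness to the many ways
real field data violate it.

## 8. Known limitations

* The ρ calibration is weakly identified on sparse benchmarks (section 6);
  the package surfaces non-attainment rather than fabricating a fit.
* The estimator is intentionally biased upward (protected-area anchoring,
  posterior mass drawn toward large groups by the n^σ tilt); synthetic
  full-map totals typically overshoot the truth, consistent with its
  upper-limit purpose.
* Bound ordering (lower ≤ best ≤ upper) is inherited from the anchors;
  with strong shape differences between the ρ = 0 and ρ = 1 curves an
  inversion is possible on regions very unlike the benchmark, and is
  logged rather than silently reordered.
* GeoTIFF support reads the minimal georeferencing tags (pixel scale,
  tiepoint, no-data) and requires square pixels.
* Curve values denote expected individuals per 1.143 km² spot; the
  groups-per-km² conversion divides the curve mean by the spot area
  verbatim.
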