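"""Curve tensor, region estimation, densities, and reporting."""

import json

import numpy as np
import pytest

from habpop.calibration import CalibrationScale, parametric_diffusion
from habpop.errors import ValidationError
from habpop.extrapolation import (
    FULL_THRESHOLDS,
    AbundanceCurve,
    CurveTensor,
    RegionEstimate,
    build_curve_tensor,
    estimate_region,
    group_density,
    mean_curve,
    region_totals,
    report,
    spot_population,
)
from habpop.calibration import SpotSummary
from habpop.raster import N_BINS, HabitatHistogram


def summary_one_bin(bin_index, mean, n_spots):
    counts = np.zeros(N_BINS)
    means = np.full(N_BINS, np.nan)
    counts[bin_index] = n_spots
    means[bin_index] = mean
    return SpotSummary(spots_count=counts, mean_expected=means)


class TestSpotPopulation:
    def test_toy_continuation_equals_benchmark_target(self):
        """mean 20 x 2 spots x parametric 1.25 = 50, the anchoring target."""
        summ = summary_one_bin(100, 20.0, 2)
        raw = np.full(N_BINS, 4.0)
        par = parametric_diffusion(raw, CalibrationScale(factor=5.0, rho=0.5, threshold=0))
        assert spot_population(summ, par, 100) == pytest.approx(50.0)

    def test_binless_spot_population_is_zero(self):
        summ = summary_one_bin(100, 20.0, 2)
        par = np.ones(N_BINS)
        assert spot_population(summ, par, 50) == 0.0

    def test_linear_in_parametric(self):
        summ = summary_one_bin(100, 20.0, 2)
        par = np.ones(N_BINS)
        assert spot_population(summ, par * 2, 100) == pytest.approx(
            2 * spot_population(summ, par, 100)
        )


class TestCurveTensor:
    def test_constant_values_pass_through(self):
        """Filters and the spline both preserve constants."""
        values = np.full(N_BINS, 3.25)
        tensor = build_curve_tensor(values, [0, 10, 100], [0, 10, 100])
        for i in range(3):
            for j in range(3):
                np.testing.assert_allclose(tensor.entry(i, j), 3.25, atol=1e-8)
        curve = mean_curve(tensor)
        np.testing.assert_allclose(curve.values, 3.25, atol=1e-8)
        # sd is sqrt of a cancellation-prone difference; only noise remains
        np.testing.assert_allclose(curve.sd, 0.0, atol=1e-6)

    def test_identity_entry_interpolates_data(self, rng):
        """t1 = t2 = 0 with data at every bin and zero smoothing returns the
        raw per-bin values."""
        values = rng.uniform(0.5, 2.0, N_BINS)
        tensor = build_curve_tensor(values, [0], [0], smoothing=0.0)
        np.testing.assert_allclose(tensor.entry(0, 0), values, atol=1e-8)

    def test_sparse_support_spline_degree_reduction(self, caplog):
        values = np.full(N_BINS, np.nan)
        values[[100, 300]] = [1.0, 2.0]
        with caplog.at_level("WARNING"):
            tensor = build_curve_tensor(values, [0], [0], smoothing=0.0)
        assert "degree reduced" in caplog.text
        entry = tensor.entry(0, 0)
        assert entry[100] == pytest.approx(1.0, abs=1e-8)
        assert entry[300] == pytest.approx(2.0, abs=1e-8)

    def test_clipping_keeps_curves_nonnegative(self, rng):
        values = np.full(N_BINS, np.nan)
        bins = rng.choice(N_BINS, 25, replace=False)
        values[bins] = rng.uniform(0, 5, 25)
        tensor = build_curve_tensor(values, [0, 3, 30], [0, 3, 30])
        assert np.all(tensor.splined >= 0)

    def test_full_resolution_bookkeeping(self):
        """The full threshold grid has 684 values per axis: 467,856 entries."""
        assert len(FULL_THRESHOLDS) == 684
        tensor = CurveTensor(
            t1_grid=FULL_THRESHOLDS,
            t2_grid=FULL_THRESHOLDS,
            splined=np.zeros((684, N_BINS)),
        )
        assert tensor.n_entries == 467_856

    def test_quadrature_weights_uniform_at_full_resolution(self):
        tensor = CurveTensor(
            t1_grid=FULL_THRESHOLDS,
            t2_grid=FULL_THRESHOLDS,
            splined=np.zeros((684, N_BINS)),
        )
        np.testing.assert_allclose(tensor.axis_weights(0), 1.0 / 684, atol=1e-12)

    def test_no_data_rejected(self):
        with pytest.raises(ValidationError):
            build_curve_tensor(np.full(N_BINS, np.nan), [0], [0])


class TestMeanCurve:
    def test_two_entry_average(self):
        values = np.full(N_BINS, 2.0)
        tensor = build_curve_tensor(values, [0], [0])
        # doctor a second t1 row with a zero curve to check plain averaging
        tensor2 = CurveTensor(
            t1_grid=(0, 1),
            t2_grid=(0,),
            splined=np.stack([np.full(N_BINS, 2.0), np.zeros(N_BINS)]),
        )
        curve = mean_curve(tensor2)
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-12)
        del tensor

    def test_mean_bounded_by_entry_extremes(self, rng):
        values = np.full(N_BINS, np.nan)
        bins = rng.choice(N_BINS, 40, replace=False)
        values[bins] = rng.uniform(0, 3, 40)
        tensor = build_curve_tensor(values, [0, 20, 200], [0, 20, 200])
        entries = np.stack([tensor.entry(i, j) for i in range(3) for j in range(3)])
        curve = mean_curve(tensor)
        assert np.all(curve.values <= entries.max(axis=0) + 1e-9)
        assert np.all(curve.values >= entries.min(axis=0) - 1e-9)


class TestEstimateRegion:
    def test_unit_curve_counts_pixels(self, rng):
        counts = rng.integers(0, 9, N_BINS)
        hist = HabitatHistogram(counts=counts)
        curve = AbundanceCurve(values=np.ones(N_BINS))
        assert estimate_region(curve, hist) == counts.sum()

    def test_additive_over_disjoint_regions(self, rng):
        curve = AbundanceCurve(values=rng.uniform(0, 2, N_BINS))
        a = rng.integers(0, 5, N_BINS)
        b = rng.integers(0, 5, N_BINS)
        est = lambda c: estimate_region(curve, HabitatHistogram(counts=c))
        assert est(a) + est(b) == pytest.approx(est(a + b), rel=1e-12)

    def test_region_totals_match_entrywise_estimates(self, rng):
        values = np.full(N_BINS, np.nan)
        bins = rng.choice(N_BINS, 30, replace=False)
        values[bins] = rng.uniform(0, 3, 30)
        tensor = build_curve_tensor(values, [0, 50], [0, 50])
        counts = rng.integers(0, 10, N_BINS)
        hist = HabitatHistogram(counts=counts)
        totals = region_totals(tensor, hist)
        assert totals.shape == (2, 2)
        assert totals[1, 0] == pytest.approx(float(tensor.entry(1, 0) @ counts))


class TestGroupDensity:
    def test_published_density_arithmetic(self):
        assert round(group_density(0.530, 1.143), 3) == 0.464

    def test_zero(self):
        assert group_density(0.0, 1.143) == 0.0

    def test_unrounded_inputs(self):
        assert group_density(1.052, 1.143) == pytest.approx(0.9204, abs=5e-4)

    def test_bad_area(self):
        with pytest.raises(ValidationError):
            group_density(1.0, 0.0)


class TestReport:
    def regions(self):
        return [
            RegionEstimate("cambodia", 37768, 75544, 150142, 275, group="high"),
            RegionEstimate("laos", 5439, 10933, 21774, 105, group="high"),
            RegionEstimate("malaysia", 59319, 119499, 238905, 105, group="high"),
            RegionEstimate("vietnam", 31794, 63953, 127704, 253, group="high"),
        ]

    def test_aggregate_is_exact_sum(self, tmp_path):
        doc = report(self.regions(), tmp_path / "regions")
        agg = {r["tag"]: r for r in doc["regions"] if r["kind"] == "aggregate"}
        assert agg["high"]["best"] == 269_929
        assert agg["total"]["best"] == 269_929
        assert agg["high"]["lower"] == sum(r.lower for r in self.regions())

    def test_order_invariant_output(self, tmp_path):
        doc1 = report(self.regions(), tmp_path / "a")
        doc2 = report(list(reversed(self.regions())), tmp_path / "b")
        assert doc1 == doc2
        assert (tmp_path / "a.csv").read_text() == (tmp_path / "b.csv").read_text()

    def test_files_written_and_parseable(self, tmp_path):
        report(self.regions(), tmp_path / "out" / "regions")
        payload = json.loads((tmp_path / "out" / "regions.json").read_text())
        assert len(payload["regions"]) == 4 + 2  # rows + group aggregate + total
        lines = (tmp_path / "out" / "regions.csv").read_text().strip().splitlines()
        assert lines[0] == "region,kind,lower,best,upper,spread"

    def test_empty_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            report([], tmp_path / "r")

    def test_rounding_half_up_only_at_output(self, tmp_path):
        doc = report([RegionEstimate("x", 0.5, 1.5, 2.5, 0.0)], tmp_path / "r")
        row = doc["regions"][0]
        assert (row["lower"], row["best"], row["upper"]) == (1, 2, 3)
        assert row["best_exact"] == 1.5
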