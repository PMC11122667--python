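"""Conditional group-size model: shapes, distributions, expectations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from habpop.errors import InvalidParameterError
from habpop.group_size import (
    NO_CROSSOVER,
    SpeciesParams,
    adjusted_signals,
    base_density,
    conditional_distribution,
    crossover_signal,
    expectation_curve,
    expected_group_size,
    lognormal_shape,
    ways_count,
)

RHO_SANCTUARY = 0.523813


class TestLogNormalShape:
    @pytest.mark.parametrize(
        "mean,sd,z,m",
        [
            (20.0, 15.0, 0.66805, 2.77259),
            (170.0, 30.0, 0.17512, 5.12047),
        ],
    )
    def test_frozen_shape_values(self, mean, sd, z, m):
        shape = lognormal_shape(mean, sd)
        assert shape.scale == pytest.approx(z, abs=1e-5)
        assert shape.location == pytest.approx(m, abs=1e-5)

    @given(
        mean=st.floats(0.5, 500.0),
        sd=st.floats(0.01, 200.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_moment_matching_by_quadrature(self, mean, sd):
        """The shape parameters reproduce the requested mean and SD."""
        shape = lognormal_shape(mean, sd)
        dist = stats.lognorm(s=shape.scale, scale=math.exp(shape.location))
        assert dist.mean() == pytest.approx(mean, rel=1e-6)
        assert dist.std() == pytest.approx(sd, rel=1e-6)

    def test_degenerate_limit_concentrates_at_one(self):
        shape = lognormal_shape(1.0, 1e-9)
        assert shape.scale == pytest.approx(0.0, abs=1e-8)
        assert shape.location == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("mean,sd", [(0.0, 1.0), (-3.0, 1.0), (5.0, 0.0), (5.0, -1.0)])
    def test_nonpositive_inputs_rejected(self, mean, sd):
        with pytest.raises(InvalidParameterError):
            lognormal_shape(mean, sd)

    def test_moment_recovery_by_sampling(self, rng):
        shape = lognormal_shape(20.0, 15.0)
        draws = rng.lognormal(shape.location, shape.scale, size=100_000)
        assert draws.mean() == pytest.approx(20.0, abs=0.3)
        assert draws.std() == pytest.approx(15.0, abs=0.5)


class TestBaseDensity:
    def test_normalized(self, params):
        for mixture in ("geometric", "arithmetic"):
            w = base_density(params, mixture)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(w >= 0)

    def test_nonprovisioned_mode_dominates(self, params):
        """ProvRt = 0.025 keeps most mass near the nonprovisioned mean."""
        for mixture in ("geometric", "arithmetic"):
            w = base_density(params, mixture)
            n = params.support
            assert w[n == 20][0] > w[n == 170][0]

    def test_equal_components_collapse_to_single_lognormal(self):
        p = SpeciesParams(prov_ratio=0.5, mean_prov=20.0, sd_prov=15.0)
        w = base_density(p, "arithmetic")
        shape = lognormal_shape(20.0, 15.0)
        single = stats.lognorm.pdf(p.support, s=shape.scale, scale=math.exp(shape.location))
        single = single / single.sum()
        np.testing.assert_allclose(w, single, atol=1e-12)
        np.testing.assert_allclose(base_density(p, "geometric"), single, atol=1e-12)


class TestAdjustedSignals:
    @pytest.mark.parametrize(
        "s,rho,expected",
        [(960, 1.0, 1.0), (7, 0.0, 7.0), (16, 0.5, 4.0)],
    )
    def test_examples(self, s, rho, expected):
        assert adjusted_signals(s, rho) == expected

    def test_endpoints_exact_over_range(self):
        for s in range(1, 10_001, 97):
            assert adjusted_signals(s, 0.0) == float(s)
            assert adjusted_signals(s, 1.0) == 1.0

    def test_invalid_signal_count(self):
        with pytest.raises(InvalidParameterError):
            adjusted_signals(0, 0.5)


class TestWaysCount:
    @pytest.mark.parametrize("n,s,expected", [(10, 3, 1000), (7, 3, 343), (5, 0, 1)])
    def test_examples(self, n, s, expected):
        assert ways_count(n, s) == expected

    def test_exact_big_integer(self):
        assert ways_count(200, 50) == 200**50


class TestConditionalDistribution:
    @given(
        s=st.integers(1, 10**6),
        rho=st.floats(0.0, 1.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_normalization(self, params, s, rho):
        cd = conditional_distribution(s, rho, params)
        assert cd.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(cd.probabilities >= 0)
        assert np.all(np.isfinite(cd.probabilities))

    def test_rho_one_is_signal_invariant(self, params):
        a = conditional_distribution(1, 1.0, params)
        b = conditional_distribution(50, 1.0, params)
        np.testing.assert_allclose(a.probabilities, b.probabilities, atol=1e-14)

    def test_toy_uniform_base_oracle(self):
        """Support {2,3}, uniform base, s=1: P ∝ n, so (0.4, 0.6)."""
        p = SpeciesParams(
            n_min=2, n_max=3, mean_nonprov=2.2, mean_prov=2.8,
            sd_nonprov=0.5, sd_prov=0.5, prov_ratio=0.1,
        )
        cd = conditional_distribution(1, 0.0, p, base_weights=np.array([1.0, 1.0]))
        np.testing.assert_allclose(cd.probabilities, [0.4, 0.6], atol=1e-12)
        assert expected_group_size(1, 0.0, p, base_weights=np.array([1.0, 1.0])) == pytest.approx(
            2.6, abs=1e-12
        )

    def test_mass_concentrates_at_n_max_for_large_s(self, params):
        cd = conditional_distribution(10**8, RHO_SANCTUARY, params)
        assert cd.prob(200) >= 1.0 - 1e-6

    @pytest.mark.parametrize("s", [1, 2, 3, 5])
    def test_log_domain_matches_direct_enumeration(self, s):
        """On a small support the log-domain path equals naive evaluation."""
        p = SpeciesParams(n_min=3, n_max=8, mean_nonprov=4.0, sd_nonprov=1.0,
                          mean_prov=7.0, sd_prov=1.0, prov_ratio=0.2)
        for rho in (0.0, 0.4, 1.0):
            cd = conditional_distribution(s, rho, p, mixture="geometric")
            n = p.support.astype(float)
            sigma = float(s) ** (1.0 - rho)

            def ln_pdf(x, mean, sd):
                z = math.sqrt(math.log(1 + (sd / mean) ** 2))
                m = math.log(mean**2 / math.sqrt(mean**2 + sd**2))
                return stats.lognorm.pdf(x, s=z, scale=math.exp(m))

            base = ln_pdf(n, 4.0, 1.0) ** 0.8 * ln_pdf(n, 7.0, 1.0) ** 0.2
            direct = base * n**sigma
            direct = direct / direct.sum()
            np.testing.assert_allclose(cd.probabilities, direct, atol=1e-12)


class TestExpectedGroupSize:
    def test_monotone_in_s(self, params):
        for rho in (0.0, RHO_SANCTUARY, 1.0):
            curve = expectation_curve(rho, params)
            values = curve(np.arange(1, 501))
            assert np.all(np.diff(values) >= -1e-9)

    def test_nonincreasing_in_rho(self, params):
        """Larger rho means fewer effective signals, hence smaller tilt."""
        for s in (2, 10, 80, 400):
            e = [expected_group_size(s, rho, params) for rho in (0.0, 0.3, 0.7, 1.0)]
            assert all(a >= b - 1e-9 for a, b in zip(e, e[1:]))

    def test_bounds(self, params):
        for s in (1, 7, 100, 10**5):
            e = expected_group_size(s, RHO_SANCTUARY, params)
            assert params.n_min <= e <= params.n_max

    def test_large_s_approaches_n_max(self, params):
        assert expected_group_size(10**8, RHO_SANCTUARY, params) == pytest.approx(200.0, abs=1e-3)

    def test_curve_caching_matches_scalar_path(self, params):
        curve = expectation_curve(RHO_SANCTUARY, params)
        for s in (1, 45, 200):
            assert curve(s) == pytest.approx(expected_group_size(s, RHO_SANCTUARY, params))


class TestCrossoverSignal:
    def test_provisioned_dominant_from_start(self):
        p = SpeciesParams(prov_ratio=0.999)
        assert crossover_signal(0.5, p) == 1

    def test_rho_one_constant_in_s(self, params):
        """sigma is pinned at 1, so dominance cannot depend on s."""
        assert crossover_signal(1.0, params) in (1, NO_CROSSOVER)

    def test_frozen_default_values(self, params):
        """Regression freeze of the dominance switch under both mixtures."""
        assert crossover_signal(RHO_SANCTUARY, params, mixture="geometric") == 27
        assert crossover_signal(RHO_SANCTUARY, params, mixture="arithmetic") == 5
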