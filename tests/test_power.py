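"""Power curves, effect priors, and the catch-all Type II error."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from plausitest import (
    Alternative,
    AlternativeSet,
    DomainError,
    EffectPrior,
    PowerCurve,
    f_test_variance_power,
    integrate_power_over_prior,
    levene_power_mc,
    mixture_type2_error,
    region_prior_mass,
)


class TestMixtureType2Error:
    def test_single_alternative_is_its_miss_probability(self):
        alts = AlternativeSet((Alternative(2.0, power=0.8),))
        assert mixture_type2_error(alts) == pytest.approx(0.2)

    def test_equal_weights_average_miss_probabilities(self):
        alts = AlternativeSet((Alternative(2.0, 0.8), Alternative(4.0, 0.6)))
        assert mixture_type2_error(alts) == pytest.approx(0.3)

    def test_unnormalised_weights_are_normalised(self):
        alts = AlternativeSet((Alternative(2.0, 0.9, weight=3.0), Alternative(4.0, 0.5, 1.0)))
        assert mixture_type2_error(alts) == pytest.approx((0.1 * 3 + 0.5 * 1) / 4)

    @settings(derandomize=True, max_examples=100)
    @given(
        powers=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8),
        weights=st.lists(st.floats(0.01, 10.0), min_size=8, max_size=8),
    )
    def test_mixture_stays_inside_convex_hull(self, powers, weights):
        alts = AlternativeSet(
            tuple(
                Alternative(float(i + 1), p, w)
                for i, (p, w) in enumerate(zip(powers, weights))
            )
        )
        beta = mixture_type2_error(alts)
        misses = [1.0 - p for p in powers]
        assert min(misses) - 1e-12 <= beta <= max(misses) + 1e-12

    def test_degenerate_sets_rejected(self):
        with pytest.raises(DomainError):
            AlternativeSet(())
        with pytest.raises(DomainError):
            AlternativeSet((Alternative(2.0, 0.5, 0.0),))  # zero total weight
        with pytest.raises(DomainError):
            AlternativeSet((Alternative(2.0, 0.5), Alternative(2.0, 0.6)))


class TestFTestPower:
    def test_size_equals_alpha_at_the_null(self):
        for n1, n2 in ((5, 5), (21, 21), (10, 40)):
            assert f_test_variance_power(1.0, n1, n2, 0.05) == pytest.approx(0.05, abs=1e-12)

    def test_power_tends_to_one_for_large_violations(self):
        assert f_test_variance_power(1e6, 21, 21, 0.05) > 0.9999

    @settings(derandomize=True, max_examples=100)
    @given(
        delta=st.floats(0.05, 20.0),
        n1=st.integers(3, 60),
        n2=st.integers(3, 60),
    )
    def test_reciprocal_relabelling_symmetry(self, delta, n1, n2):
        a = f_test_variance_power(delta, n1, n2, 0.05)
        b = f_test_variance_power(1.0 / delta, n2, n1, 0.05)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)

    def test_monotone_in_log_ratio_magnitude_and_sample_size(self):
        deltas = np.exp(np.linspace(0.0, 3.0, 15))
        powers = f_test_variance_power(deltas, 21, 21, 0.05)
        assert np.all(np.diff(powers) > 0)
        assert f_test_variance_power(4.0, 41, 41, 0.05) > f_test_variance_power(4.0, 21, 21, 0.05)

    def test_exceeds_alpha_off_the_null(self):
        """Any real violation is detected more often than a true null at moderate n."""
        deltas = np.exp(np.linspace(-3, 3, 41))
        powers = f_test_variance_power(deltas, 30, 30, 0.05)
        off_null = np.abs(np.log(deltas)) > 1e-9
        assert np.all(powers[off_null] > 0.05)

    def test_agrees_with_data_level_simulation(self):
        """MC oracle: simulate Gaussian data, apply the F test, compare rates."""
        reps, n1, n2, delta = 200_000, 21, 21, 4.0
        rng = np.random.default_rng(2024)
        v1 = delta * rng.chisquare(n1 - 1, reps) / (n1 - 1)
        v2 = rng.chisquare(n2 - 1, reps) / (n2 - 1)
        lo = stats.f.ppf(0.025, n1 - 1, n2 - 1)
        hi = stats.f.isf(0.025, n1 - 1, n2 - 1)
        ratio = v1 / v2
        rate = np.mean((ratio < lo) | (ratio > hi))
        se = math.sqrt(rate * (1 - rate) / reps)
        assert f_test_variance_power(delta, n1, n2, 0.05) == pytest.approx(rate, abs=3 * se)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(DomainError):
            f_test_variance_power(0.0, 21, 21)
        with pytest.raises(DomainError):
            f_test_variance_power(2.0, 1, 21)


class TestLevenePowerMC:
    def test_seeded_determinism(self):
        a = levene_power_mc(2.0, 20, 20, nsim=500, seed=11)
        b = levene_power_mc(2.0, 20, 20, nsim=500, seed=11)
        assert a == b

    def test_large_violation_power_near_one(self):
        rate, _ = levene_power_mc(16.0, 50, 50, nsim=4000, seed=3)
        assert rate > 0.99

    def test_size_near_nominal_at_the_null(self):
        # mean-centred Levene is known to be slightly liberal at n = 50;
        # the band asserts the documented finite-sample behaviour.
        rate, _ = levene_power_mc(1.0, 50, 50, nsim=20_000, seed=5)
        assert 0.045 <= rate <= 0.062

    def test_nsim_floor_enforced(self):
        with pytest.raises(DomainError):
            levene_power_mc(2.0, 20, 20, nsim=50)


class TestEffectPrior:
    def test_lognormal_weights_normalised_on_increasing_grid(self):
        prior = EffectPrior.lognormal()
        assert prior.weights.sum() == pytest.approx(1.0)
        assert np.all(np.diff(prior.nodes) > 0)

    def test_full_support_region_mass_is_one(self):
        prior = EffectPrior.lognormal()
        assert region_prior_mass(prior, 1e-8, 1e8) == pytest.approx(1.0, abs=1e-9)

    def test_region_without_mass_is_zero(self):
        prior = EffectPrior.from_nodes([math.log(4.0)], [1.0])
        assert region_prior_mass(prior, 10.0, 20.0) == 0.0

    def test_decade_region_matches_lognormal_cdf(self):
        prior = EffectPrior.lognormal(median=1.0, sigma_log=0.7)
        expected = stats.lognorm(s=0.7, scale=1.0).cdf(10.0) - stats.lognorm(
            s=0.7, scale=1.0
        ).cdf(0.1)
        assert region_prior_mass(prior, 0.1, 10.0) == pytest.approx(expected, abs=1e-9)

    def test_point_mass_on_null_counts_when_region_covers_one(self):
        prior = EffectPrior.from_nodes(
            [math.log(4.0)], [1.0], point_mass_on_null=0.3
        )
        assert region_prior_mass(prior, 0.5, 2.0) == pytest.approx(0.3)
        assert region_prior_mass(prior, 2.0, 8.0) == pytest.approx(0.7)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(DomainError):
            region_prior_mass(EffectPrior.lognormal(), 10.0, 0.1)

    def test_serialisation_round_trip(self):
        for prior in (
            EffectPrior.lognormal(median=2.0, sigma_log=0.5),
            EffectPrior.point_mass(3.0),
            EffectPrior.from_nodes([-1.0, 0.5, 1.0], [0.2, 0.5, 0.3], 0.1),
        ):
            again = EffectPrior.from_dict(prior.to_dict())
            assert np.allclose(again.nodes, prior.nodes)
            assert np.allclose(again.weights, prior.weights)
            assert again.point_mass_on_null == prior.point_mass_on_null

    def test_unknown_keys_rejected(self):
        with pytest.raises(DomainError):
            EffectPrior.from_dict({"family": "lognormal", "params": [1, 0.7], "junk": 1})

    def test_continuous_sampling_matches_family(self):
        prior = EffectPrior.lognormal(median=1.0, sigma_log=0.7)
        draws = prior.sample(np.random.default_rng(1), 50_000)
        assert np.median(np.log(draws)) == pytest.approx(0.0, abs=0.02)
        assert np.std(np.log(draws)) == pytest.approx(0.7, abs=0.02)


class TestIntegratePowerOverPrior:
    def test_point_prior_recovers_pointwise_power(self):
        curve = PowerCurve.f_test(21, 21, 0.05)
        prior = EffectPrior.point_mass(4.0)
        assert integrate_power_over_prior(curve, prior) == pytest.approx(
            f_test_variance_power(4.0, 21, 21, 0.05)
        )

    def test_symmetric_prior_equals_doubled_half_prior(self):
        """With equal n the power curve is log-symmetric, so only |log delta| matters."""
        curve = PowerCurve.f_test(21, 21, 0.05)
        full = integrate_power_over_prior(curve, EffectPrior.lognormal(1.0, 0.7, 81))
        # fold the prior onto delta >= 1: same expectation by symmetry
        grid = np.linspace(0, 4.6, 41)
        dens = 2.0 * stats.norm.pdf(grid, 0.0, 0.7)
        w = dens.copy()
        w[1:-1] *= (grid[2] - grid[0]) / 2
        w[0] *= (grid[1] - grid[0]) / 2  # node 0 appears once, not twice
        w[-1] *= (grid[-1] - grid[-2]) / 2
        folded = EffectPrior.from_nodes(grid, w)
        assert integrate_power_over_prior(curve, folded) == pytest.approx(full, abs=2e-3)

    def test_quadrature_matches_hierarchical_simulation(self):
        """Draw delta from the continuous prior, simulate data, test: rates agree."""
        n1 = n2 = 21
        curve = PowerCurve.f_test(n1, n2, 0.05)
        prior = EffectPrior.lognormal(median=1.0, sigma_log=0.7)
        quad = integrate_power_over_prior(curve, prior)
        reps = 100_000
        rng = np.random.default_rng(99)
        deltas = prior.sample(rng, reps)
        v1 = deltas * rng.chisquare(n1 - 1, reps) / (n1 - 1)
        v2 = rng.chisquare(n2 - 1, reps) / (n2 - 1)
        lo = stats.f.ppf(0.025, n1 - 1, n2 - 1)
        hi = stats.f.isf(0.025, n1 - 1, n2 - 1)
        rate = np.mean((v1 / v2 < lo) | (v1 / v2 > hi))
        se = math.sqrt(rate * (1 - rate) / reps)
        assert quad == pytest.approx(rate, abs=3 * se)


class TestPowerMatching:
    def test_bisection_hits_target_on_exact_curve(self):
        curve = PowerCurve.f_test(50, 50, 0.05)
        delta = curve.match_power(0.90, tol=1e-4)
        assert f_test_variance_power(delta, 50, 50, 0.05) == pytest.approx(0.90, abs=1e-3)

    def test_unattainable_power_raises(self):
        curve = PowerCurve.f_test(3, 3, 0.05)
        with pytest.raises(DomainError):
            curve.match_power(0.99, hi=1.5)

    def test_levene_mc_curve_is_monotone_under_common_random_numbers(self):
        curve = PowerCurve.levene_mc(30, 30, 0.05, nsim=4000, seed=8)
        powers = curve(np.array([1.0, 2.0, 4.0, 8.0]))
        assert np.all(np.diff(powers) > 0)
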