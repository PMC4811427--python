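"""Tests of the direct and least-squares incidence estimators."""

import numpy as np
import pytest

from previnc import cross_sections_from_surface
from previnc.estimators import (
    CrossSection,
    SingularPrevalenceError,
    characteristic_derivative,
    chi_square,
    direct_incidence,
    estimate_series,
    ls_incidence,
    midpoint_prevalence,
    predict_cross_sections,
    trend_fit,
)
from previnc.idm_model import MortalityInput, pde_rhs_excess


def make_cs(time, ages, p, sigma=None):
    return CrossSection(time=time, ages=np.asarray(ages, float), p=np.asarray(p, float), sigma=sigma)


@pytest.fixture()
def simple_pair():
    ages = np.arange(60.0, 71.0)
    p1 = 0.05 + 0.002 * (ages - 60.0)
    p2 = p1 + 0.004
    return make_cs(2000.0, ages, p1), make_cs(2001.0, ages, p2)


def mort_for(ages, m=0.02, R=2.0, time=2000.5):
    ages = np.asarray(ages, float)
    return MortalityInput(time=time, ages=ages, m=np.full_like(ages, m), R=np.full_like(ages, R))


class TestMidpointPrevalence:
    def test_symmetric_weights_average_the_two_nodes(self, simple_pair):
        cs1, cs2 = simple_pair
        got = midpoint_prevalence(cs1, cs2, 2000.5, 65.5)
        assert got == pytest.approx((cs1.value_at(65.0) + cs2.value_at(66.0)) / 2.0, abs=1e-15)

    def test_preserves_constants(self):
        ages = np.arange(60.0, 66.0)
        cs1 = make_cs(2000.0, ages, np.full(6, 0.07))
        cs2 = make_cs(2001.0, ages, np.full(6, 0.07))
        assert midpoint_prevalence(cs1, cs2, 2000.25, 62.25) == pytest.approx(0.07, abs=1e-15)

    def test_missing_age_node_is_named(self, simple_pair):
        cs1, cs2 = simple_pair
        with pytest.raises(ValueError, match="node"):
            midpoint_prevalence(cs1, cs2, 2000.5, 65.0)  # needs 64.5/65.5, not on grid

    def test_requires_t_star_between_surveys(self, simple_pair):
        cs1, cs2 = simple_pair
        with pytest.raises(ValueError, match="t1 < t"):
            midpoint_prevalence(cs1, cs2, 1999.5, 65.5)


class TestCharacteristicDerivative:
    def test_zero_for_constant_prevalence(self):
        ages = np.arange(60.0, 66.0)
        cs1 = make_cs(2000.0, ages, np.full(6, 0.07))
        cs2 = make_cs(2001.0, ages, np.full(6, 0.07))
        assert characteristic_derivative(cs1, cs2, 2000.5, 62.5) == 0.0

    def test_hand_value(self):
        cs1 = make_cs(2000.0, [65.0], [0.10])
        cs2 = make_cs(2001.0, [66.0], [0.11])
        assert characteristic_derivative(cs1, cs2, 2000.5, 65.5) == pytest.approx(0.01, abs=1e-15)

    def test_matches_analytic_rhs_on_simulated_surface(self, constant_rate_surface):
        """The centered difference approximates (d/dt + d/da)p at the midpoint
        to second order; oracle = the analytic right-hand side at the true p."""
        model, grid, surface = constant_rate_surface
        cs1, cs2 = cross_sections_from_surface(surface, [2004.0, 2005.0])
        a = 45.5
        got = characteristic_derivative(cs1, cs2, 2004.5, a)
        p_true = 1.0 - np.exp(-0.01 * (a - 30.0))
        want = pde_rhs_excess(p_true, 0.01, 0.02, 0.02)
        assert got == pytest.approx(want, abs=1e-6)


class TestDirectIncidence:
    def test_zero_prevalence_gives_zero_incidence(self):
        ages = np.arange(60.0, 66.0)
        cs1 = make_cs(2000.0, ages, np.zeros(6))
        cs2 = make_cs(2001.0, ages, np.zeros(6))
        est = direct_incidence(cs1, cs2, mort_for(ages[:-1] + 0.5))
        assert np.all(est.incidence == 0.0)
        assert not est.clamped.any()

    def test_stationary_prevalence_with_unit_rate_ratio(self):
        ages = np.arange(60.0, 66.0)
        p = np.full(6, 0.08)
        est = direct_incidence(
            make_cs(2000.0, ages, p), make_cs(2001.0, ages, p), mort_for(ages[:-1] + 0.5, R=1.0)
        )
        assert np.allclose(est.incidence, 0.0, atol=1e-15)

    def test_recovers_constant_incidence_from_simulation(self, constant_rate_surface):
        model, grid, surface = constant_rate_surface
        cs1, cs2 = cross_sections_from_surface(surface, [2004.0, 2005.0])
        ages = grid.ages[:-1] + 0.5
        est = direct_incidence(cs1, cs2, mort_for(ages, m=0.02, R=1.0, time=2004.5))
        assert np.max(np.abs(est.incidence - 0.01) / 0.01) < 1e-4

    def test_forced_negative_estimate_is_clamped_and_flagged(self):
        ages = np.arange(60.0, 66.0)
        est = direct_incidence(
            make_cs(2000.0, ages, np.full(6, 0.2)),
            make_cs(2001.0, ages, np.full(6, 0.1)),
            mort_for(ages[:-1] + 0.5, m=0.001, R=1.0),
        )
        assert np.all(est.incidence == 0.0)
        assert est.clamped.all()

    def test_prevalence_near_one_raises_singularity_error(self):
        ages = np.arange(60.0, 63.0)
        p = np.array([1.0 - 1e-12, 1.0 - 1e-12, 1.0 - 1e-12])
        with pytest.raises(SingularPrevalenceError):
            direct_incidence(
                make_cs(2000.0, ages, p), make_cs(2001.0, ages, p), mort_for(ages[:-1] + 0.5)
            )

    def test_mortality_must_cover_estimation_ages(self, simple_pair):
        cs1, cs2 = simple_pair
        with pytest.raises(ValueError, match="cover"):
            direct_incidence(cs1, cs2, mort_for(np.array([60.5, 61.5])))


class TestLeastSquares:
    def test_identical_to_direct_on_noise_free_equal_sigma(self, danish_validation):
        """The closed-form LS solution collapses onto the direct inversion when
        there is no sampling noise and all weights are equal."""
        for e_d, e_ls in zip(
            danish_validation.estimates["direct"], danish_validation.estimates["least_squares"]
        ):
            np.testing.assert_allclose(e_ls.incidence, e_d.incidence, rtol=1e-10, atol=1e-14)

    def test_infinite_sigma_on_one_side_defers_to_the_other(self, simple_pair):
        cs1, cs2 = simple_pair
        mort = mort_for(cs1.ages[:-1] + 0.5)
        big = 1e9
        cs2w = make_cs(cs2.time, cs2.ages, cs2.p, sigma=np.full(len(cs2.ages), big))
        est = ls_incidence(cs1, cs2w, mort)
        # with the t2 cells weightless, the minimiser is driven by the t1 residuals
        # alone: their predicted cells reproduce the observed p(t1, .) exactly
        i = est.incidence
        p_star = np.array([midpoint_prevalence(cs1, cs2, mort.time, a) for a in est.ages])
        _, p1_pred, _, _ = predict_cross_sections(p_star, i, mort_for(est.ages), 0.5, 0.5)
        np.testing.assert_allclose(p1_pred, cs1.p[:-1], atol=1e-9)

    def test_negative_minimum_is_projected_to_zero(self):
        ages = np.arange(60.0, 66.0)
        est = ls_incidence(
            make_cs(2000.0, ages, np.full(6, 0.2)),
            make_cs(2001.0, ages, np.full(6, 0.1)),
            mort_for(ages[:-1] + 0.5, m=0.001, R=1.0),
        )
        assert np.all(est.incidence == 0.0)
        assert est.clamped.all()

    def test_closed_form_agrees_with_numeric_scalar_minimisation(self, simple_pair):
        """Independent oracle: bounded scalar search on the chi-square objective."""
        from scipy.optimize import minimize_scalar

        cs1, cs2 = simple_pair
        rng = np.random.default_rng(5)
        s1 = rng.uniform(0.002, 0.01, len(cs1.ages))
        s2 = rng.uniform(0.002, 0.01, len(cs2.ages))
        cs1w = make_cs(cs1.time, cs1.ages, cs1.p, sigma=s1)
        cs2w = make_cs(cs2.time, cs2.ages, cs2.p + rng.normal(0, 0.002, len(cs2.ages)) ** 2, sigma=s2)
        mort = mort_for(cs1.ages[:-1] + 0.5)
        est = ls_incidence(cs1w, cs2w, mort)
        for k in [0, 4, 9]:
            base = est.incidence.copy()

            def objective(x):
                guess = base.copy()
                guess[k] = x
                return chi_square(guess, cs1w, cs2w, mort)

            res = minimize_scalar(objective, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-12})
            assert objective(est.incidence[k]) <= res.fun + 1e-10


class TestChiSquare:
    def test_zero_when_guess_reproduces_observations(self, constant_rate_surface):
        model, grid, surface = constant_rate_surface
        cs1, cs2 = cross_sections_from_surface(surface, [2004.0, 2005.0])
        mort = mort_for(grid.ages[:-1] + 0.5, m=0.02, R=1.0, time=2004.5)
        est = ls_incidence(cs1, cs2, mort)
        assert chi_square(est.incidence, cs1, cs2, mort) < 1e-10

    def test_doubling_all_sigmas_quarters_the_score(self, simple_pair):
        cs1, cs2 = simple_pair
        mort = mort_for(cs1.ages[:-1] + 0.5)
        guess = np.full(len(cs1.ages) - 1, 0.01)
        s = np.full(len(cs1.ages), 0.005)
        x1 = chi_square(guess, make_cs(2000.0, cs1.ages, cs1.p, s), make_cs(2001.0, cs2.ages, cs2.p, s), mort)
        x2 = chi_square(
            guess, make_cs(2000.0, cs1.ages, cs1.p, 2 * s), make_cs(2001.0, cs2.ages, cs2.p, 2 * s), mort
        )
        assert x1 == pytest.approx(4.0 * x2, rel=1e-12)

    def test_single_cell_residual_value(self):
        """One residual of 0.01 at sigma 0.005 scores (0.01/0.005)^2 = 4."""
        cs1 = make_cs(2000.0, [65.0, 66.0], [0.10, 0.10])
        cs2 = make_cs(2001.0, [65.0, 66.0], [0.10, 0.10])
        mort = mort_for([65.5], m=0.0, R=1.0)
        # guess that propagates p* = 0.10 to exactly 0.11 at t2 (residual 0.01)
        # and 0.09 at t1 (residual -0.01): rhs = (1-p*) * i = 0.02 => step 0.01
        guess = np.array([0.02 / 0.9])
        huge = np.array([1e9, 1e9])  # weightless cells
        sig_one = np.array([0.005, 1e9])  # only the (t1, 65) cell carries weight
        sig_two = np.array([1e9, 0.005])  # only the (t2, 66) cell carries weight
        x = chi_square(
            guess,
            make_cs(2000.0, [65.0, 66.0], [0.10, 0.10], sig_one),
            make_cs(2001.0, [65.0, 66.0], [0.10, 0.10], huge),
            mort,
        )
        assert x == pytest.approx(4.0, rel=1e-9)
        x = chi_square(
            guess,
            make_cs(2000.0, [65.0, 66.0], [0.10, 0.10], huge),
            make_cs(2001.0, [65.0, 66.0], [0.10, 0.10], sig_two),
            mort,
        )
        assert x == pytest.approx(4.0, rel=1e-9)


class TestPredictCrossSections:
    def test_zero_offsets_are_the_identity(self):
        ages = np.arange(60.0, 66.0) + 0.5
        p_star = np.linspace(0.05, 0.1, 6)
        mort = mort_for(ages)
        a1, p1, a2, p2 = predict_cross_sections(p_star, np.full(6, 0.01), mort, 0.0, 0.0)
        np.testing.assert_array_equal(p1, p_star)
        np.testing.assert_array_equal(p2, p_star)

    def test_frozen_dynamics_shift_ages_only(self):
        ages = np.arange(60.0, 66.0) + 0.5
        p_star = np.linspace(0.05, 0.1, 6)
        mort = mort_for(ages, m=0.0)
        a1, p1, a2, p2 = predict_cross_sections(p_star, np.zeros(6), mort, 0.5, 0.5)
        np.testing.assert_array_equal(p1, p_star)
        np.testing.assert_array_equal(p2, p_star)
        np.testing.assert_allclose(a1, ages - 0.5)
        np.testing.assert_allclose(a2, ages + 0.5)

    def test_first_order_consistency_with_direct_inversion(self, constant_rate_surface):
        """Propagating the direct estimate forward/backward reproduces the
        observed cross-sections up to the O(h^2) discretisation error."""
        model, grid, surface = constant_rate_surface
        cs1, cs2 = cross_sections_from_surface(surface, [2004.0, 2005.0])
        mort = mort_for(grid.ages[:-1] + 0.5, m=0.02, R=1.0, time=2004.5)
        est = direct_incidence(cs1, cs2, mort)
        p_star = np.array([midpoint_prevalence(cs1, cs2, 2004.5, a) for a in est.ages])
        a1, p1, a2, p2 = predict_cross_sections(p_star, est.incidence, mort, 0.5, 0.5)
        np.testing.assert_allclose(p1, cs1.p[:-1], atol=5e-4)
        np.testing.assert_allclose(p2, cs2.p[1:], atol=5e-4)


class TestSeriesAndTrend:
    def test_ten_yearly_surveys_give_nine_midpoint_estimates(self, danish_validation):
        ests = danish_validation.estimates["direct"]
        assert [e.time for e in ests] == [1995.5 + k for k in range(9)]
        for e in ests:
            np.testing.assert_allclose(e.ages, np.arange(30.5, 100.0))

    def test_two_surveys_reduce_to_a_single_estimate(self, simple_pair):
        cs1, cs2 = simple_pair
        mort = mort_for(cs1.ages[:-1] + 0.5)
        series = estimate_series([cs1, cs2], [mort], method="direct")
        single = direct_incidence(cs1, cs2, mort)
        assert len(series) == 1
        np.testing.assert_array_equal(series[0].incidence, single.incidence)

    def test_input_order_is_irrelevant(self, simple_pair):
        cs1, cs2 = simple_pair
        cs3 = make_cs(2002.0, cs2.ages, cs2.p + 0.003)
        morts = [mort_for(cs1.ages[:-1] + 0.5, time=t) for t in (2000.5, 2001.5)]
        a = estimate_series([cs1, cs2, cs3], morts, method="direct")
        b = estimate_series([cs3, cs1, cs2], morts[::-1], method="direct")
        for ea, eb in zip(a, b):
            np.testing.assert_array_equal(ea.incidence, eb.incidence)

    def test_missing_midpoint_mortality_is_an_error(self, simple_pair):
        cs1, cs2 = simple_pair
        with pytest.raises(ValueError, match="midpoint"):
            estimate_series([cs1, cs2], [mort_for(cs1.ages[:-1] + 0.5, time=2000.75)])

    def test_trend_fit_is_exact_on_an_exponential_series(self):
        from previnc.estimators import IncidenceEstimate

        ests = [
            IncidenceEstimate(
                time=2000.5 + k,
                ages=np.array([65.5]),
                incidence=np.array([0.01 * 1.053**k]),
                method="direct",
            )
            for k in range(5)
        ]
        assert trend_fit(ests, 65.5) == pytest.approx(5.3, abs=1e-9)

    def test_trend_fit_constant_series_is_zero(self):
        from previnc.estimators import IncidenceEstimate

        ests = [
            IncidenceEstimate(time=2000.5 + k, ages=np.array([65.5]), incidence=np.array([0.01]), method="direct")
            for k in range(4)
        ]
        assert trend_fit(ests, 65.5) == pytest.approx(0.0, abs=1e-12)

    def test_trend_fit_rejects_clamped_zero_incidence(self):
        from previnc.estimators import IncidenceEstimate

        ests = [
            IncidenceEstimate(time=2000.5 + k, ages=np.array([65.5]), incidence=np.array([v]), method="direct")
            for k, v in enumerate([0.01, 0.0, 0.01])
        ]
        with pytest.raises(ValueError, match="another age|positive"):
            trend_fit(ests, 65.5)
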