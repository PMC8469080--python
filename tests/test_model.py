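"""Structural model: closed forms vs independent numerical oracles."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from pazopk.model import (
    DoseRegimen,
    IndividualParameters,
    PopulationParameters,
    RandomEffects,
    apply_covariates,
    auc_from_clearance,
    concentration_single_dose,
    concentration_steady_state,
    predict_concentration,
    residual_sd,
)


def ode_single_dose(ip, dose, t_grid):
    """Oracle: integrate the depot/central two-compartment ODE system."""
    def rhs(_, y):
        depot, central = y
        return [-ip.ka * depot, ip.ka * depot - ip.ke * central]

    sol = solve_ivp(rhs, (0.0, float(max(t_grid))), [dose, 0.0],
                    t_eval=np.asarray(t_grid, float), rtol=1e-10, atol=1e-12)
    return sol.y[1] / ip.v


class TestApplyCovariates:
    def test_reference_covariate_identity(self, reference_pop):
        re = RandomEffects()
        ip = apply_covariates(reference_pop, 36.5, re, "occ1")
        assert ip.v == pytest.approx(reference_pop.v_pop)
        assert ip.cl == pytest.approx(reference_pop.cl_pop)
        assert ip.ka == pytest.approx(reference_pop.ka_pop)

    def test_doubled_asat_power_term(self):
        # hand evaluation: 22.3 * 2**(-0.838) = 12.474
        pop = PopulationParameters(ka_pop=0.976, v_pop=22.3, cl_pop=0.458,
                                   beta_v_asat=-0.838)
        ip = apply_covariates(pop, 73.0, RandomEffects(), "occ1")
        assert ip.v == pytest.approx(22.3 * 2.0 ** -0.838, rel=1e-12)
        assert ip.v == pytest.approx(12.475, abs=5e-3)

    def test_null_covariate(self):
        pop = PopulationParameters(ka_pop=1.0, v_pop=22.3, cl_pop=0.5,
                                   beta_v_asat=0.0)
        for asat in (10.0, 36.5, 200.0):
            assert apply_covariates(pop, asat, RandomEffects()).v == 22.3

    def test_monotone_decreasing_in_asat_for_negative_beta(self):
        pop = PopulationParameters(ka_pop=1.0, v_pop=22.3, cl_pop=0.5,
                                   beta_v_asat=-0.838)
        asats = np.linspace(5.0, 200.0, 40)
        vs = [apply_covariates(pop, a, RandomEffects()).v for a in asats]
        assert np.all(np.diff(vs) < 0)

    def test_random_effects_enter_exponentially(self, reference_pop):
        re = RandomEffects(eta_ka=0.2, eta_v=-0.1, eta_cl=0.3,
                           kappa_v={"c": 0.05}, kappa_cl={"c": -0.05})
        ip = apply_covariates(reference_pop, 36.5, re, "c")
        assert ip.v == pytest.approx(reference_pop.v_pop * math.exp(-0.05))
        assert ip.cl == pytest.approx(reference_pop.cl_pop * math.exp(0.25))
        assert ip.ka == pytest.approx(reference_pop.ka_pop * math.exp(0.2))

    def test_errors(self, reference_pop):
        with pytest.raises(ValueError):
            apply_covariates(reference_pop, -1.0, RandomEffects())
        with pytest.raises(KeyError):
            apply_covariates(reference_pop, 36.5,
                             RandomEffects(kappa_v={"a": 0.1}), "b")


class TestSingleDose:
    def test_zero_at_dose_time(self, typical_ip):
        assert concentration_single_dose(typical_ip, 800, 0.0) == 0.0

    def test_published_typical_value_at_24h(self, typical_ip):
        # dose 800, V 22.3, ka 0.976, Cl 0.458 -> ~22.4 mg/L at 24 h
        c = concentration_single_dose(typical_ip, 800, 24.0)
        assert c == pytest.approx(22.38, abs=0.05)

    def test_matches_ode_oracle_typical(self, typical_ip):
        t = np.linspace(0.5, 96.0, 40)
        analytic = concentration_single_dose(typical_ip, 800, t)
        numeric = ode_single_dose(typical_ip, 800, t)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-6)

    def test_matches_ode_oracle_random_parameters(self, rng):
        for _ in range(100):
            ip = IndividualParameters.from_rates(
                ka=float(rng.uniform(0.05, 5.0)),
                v=float(rng.uniform(5.0, 200.0)),
                cl=float(rng.uniform(0.05, 20.0)))
            t = np.linspace(0.25, 96.0, 12)
            np.testing.assert_allclose(
                concentration_single_dose(ip, 400, t),
                ode_single_dose(ip, 400, t), rtol=1e-6, atol=1e-12)

    def test_ka_equals_ke_limit_continuity(self):
        v, cl = 20.0, 1.0
        ke = cl / v
        t = np.linspace(0.0, 48.0, 25)
        exact_limit = IndividualParameters.from_rates(ka=ke, v=v, cl=cl)
        ref = concentration_single_dose(exact_limit, 800, t)
        for rel in (1e-12, 1e-9, 1e-7, 1e-5):
            ip = IndividualParameters.from_rates(ka=ke * (1 + rel), v=v, cl=cl)
            np.testing.assert_allclose(
                concentration_single_dose(ip, 800, t), ref, rtol=1e-4, atol=1e-10)

    @given(st.floats(0.05, 5.0), st.floats(5.0, 100.0), st.floats(0.05, 5.0),
           st.floats(0.0, 200.0))
    @settings(max_examples=50, deadline=None)
    def test_non_negative_everywhere(self, ka, v, cl, t):
        ip = IndividualParameters.from_rates(ka=ka, v=v, cl=cl)
        assert concentration_single_dose(ip, 800, t) >= 0.0

    def test_negative_time_rejected(self, typical_ip):
        with pytest.raises(ValueError):
            concentration_single_dose(typical_ip, 800, -1.0)


class TestSteadyState:
    def test_trough_matches_superposition_sum(self, typical_ip):
        # oracle: explicit sum of single-dose contributions
        reg = DoseRegimen(dose=800, tau=24.0, n_doses_before_obs=10)
        ss = concentration_steady_state(typical_ip, reg, 24.0)
        brute = sum(concentration_single_dose(typical_ip, 800, 24.0 + j * 24.0)
                    for j in range(3000))
        assert ss == pytest.approx(brute, rel=1e-6)
        assert ss == pytest.approx(57.52, abs=0.05)

    def test_superposition_over_grid(self, typical_ip):
        reg = DoseRegimen(dose=400, tau=24.0, n_doses_before_obs=10)
        for t in (0.0, 0.5, 2.0, 8.0, 23.9):
            brute = sum(concentration_single_dose(typical_ip, 400, t + j * 24.0)
                        for j in range(3000))
            assert concentration_steady_state(typical_ip, reg, t) == \
                pytest.approx(brute, rel=1e-6)

    def test_finite_sum_gap_bounded_by_accumulation_envelope(self):
        ip = IndividualParameters.from_rates(ka=1.0, v=50.0, cl=1.0)  # ke=0.02
        reg = DoseRegimen(dose=800, tau=24.0, n_doses_before_obs=10)
        t = 12.0
        ten = sum(concentration_single_dose(ip, 800, t + j * 24.0)
                  for j in range(10))
        ss = concentration_steady_state(ip, reg, t)
        # the elimination-phase tail ratio is exactly exp(-10*ke*tau); the
        # absorption term adds only a vanishing correction
        assert 0 < (ss - ten) / ss < 1.001 * math.exp(-10 * 0.02 * 24.0)

    def test_no_accumulation_limit(self, typical_ip):
        # ke*tau >> 1: the steady-state curve collapses onto a single dose
        ip = IndividualParameters.from_rates(ka=5.0, v=10.0, cl=20.0)  # ke=2
        reg = DoseRegimen(dose=800, tau=24.0, n_doses_before_obs=10)
        t = np.linspace(0.1, 12.0, 15)
        np.testing.assert_allclose(
            concentration_steady_state(ip, reg, t),
            concentration_single_dose(ip, 800, t), rtol=1e-8)

    def test_steady_state_dominates_single_dose(self, typical_ip):
        reg = DoseRegimen(dose=800, tau=24.0, n_doses_before_obs=10)
        t = np.linspace(0.0, 24.0, 30)
        assert np.all(concentration_steady_state(typical_ip, reg, t)
                      >= concentration_single_dose(typical_ip, 800, t))

    def test_interval_integral_equals_dose_over_clearance(self, typical_ip):
        # Dose/Cl is the exact integral of one steady-state interval;
        # the trapezoid sum must converge to it as the grid refines
        reg = DoseRegimen(dose=800, tau=24.0, n_doses_before_obs=10)
        target = auc_from_clearance(800, typical_ip.cl)
        errs = []
        for n in (200, 800, 3200):
            t = np.linspace(0.0, 24.0, n)
            c = concentration_steady_state(typical_ip, reg, t)
            errs.append(abs(np.trapezoid(c, t) - target) / target)
        assert errs[-1] < 1e-5
        assert errs[0] > errs[1] > errs[2]

    def test_repeated_dosing_between_one_and_steady(self, typical_ip):
        reg5 = DoseRegimen(dose=800, tau=24.0, n_doses_before_obs=5)
        brute = sum(concentration_single_dose(typical_ip, 800, 6.0 + j * 24.0)
                    for j in range(5))
        assert predict_concentration(typical_ip, reg5, 6.0) == \
            pytest.approx(brute, rel=1e-9)


class TestAucAndResidual:
    @pytest.mark.parametrize("dose,cl,expected", [
        (800.0, 0.458, 1746.7), (200.0, 0.458, 436.7)])
    def test_auc_from_clearance(self, dose, cl, expected):
        auc = auc_from_clearance(dose, cl)
        assert auc == pytest.approx(expected, abs=0.05)
        assert auc * cl == pytest.approx(dose)

    def test_auc_rejects_nonpositive_clearance(self):
        with pytest.raises(ValueError):
            auc_from_clearance(800.0, 0.0)

    @pytest.mark.parametrize("a,b,pred,expected", [
        (1.5, 0.0, 7.0, 1.5),    # additive-only
        (0.0, 0.2, 10.0, 2.0),   # proportional-only
        (1.0, 0.2, 20.0, 5.0),   # combined-1
    ])
    def test_residual_sd_combined1(self, a, b, pred, expected):
        pop = PopulationParameters(ka_pop=1, v_pop=20, cl_pop=0.5,
                                   err_add=a, err_prop=b)
        assert residual_sd(pred, pop) == pytest.approx(expected)

    def test_residual_sd_combined2_option(self):
        pop = PopulationParameters(ka_pop=1, v_pop=20, cl_pop=0.5,
                                   err_add=3.0, err_prop=0.4,
                                   error_model="combined2")
        assert residual_sd(10.0, pop) == pytest.approx(5.0)

    def test_residual_rejects_negative_prediction(self, reference_pop):
        with pytest.raises(ValueError):
            residual_sd(-1.0, reference_pop)


class TestTypes:
    def test_population_parameters_validate(self):
        with pytest.raises(ValueError):
            PopulationParameters(ka_pop=-1, v_pop=20, cl_pop=0.5)
        with pytest.raises(ValueError):
            PopulationParameters(ka_pop=1, v_pop=20, cl_pop=0.5, omega_v=-0.1)

    def test_individual_ke_consistency(self):
        ip = IndividualParameters.from_rates(ka=1.0, v=20.0, cl=0.5)
        assert ip.ke == pytest.approx(0.025, rel=1e-12)
        with pytest.raises(ValueError):
            IndividualParameters(ka=1.0, v=20.0, cl=0.5, ke=0.5)

    def test_regimen_validation(self):
        with pytest.raises(ValueError):
            DoseRegimen(dose=0.0)
        assert DoseRegimen(dose=800, n_doses_before_obs=10).steady_state
        assert not DoseRegimen(dose=800, n_doses_before_obs=1).steady_state
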