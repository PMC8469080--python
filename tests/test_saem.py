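"""SAEM estimation: identifiability limits, likelihood oracles, selection."""
import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate, stats

from pazopk import (
    CohortDesign,
    PopulationParameters,
    generate_cohort,
    log_likelihood_is,
)
from pazopk.cohort import SS_N_DOSES, Cohort, Subject
from pazopk.model import (
    DoseRegimen,
    RandomEffects,
    apply_covariates,
    concentration_steady_state,
    residual_sd,
)
from pazopk.saem import (
    AIC_SIGNIFICANT_DROP,
    OFV_SIGNIFICANT_DROP,
    CovariateCandidate,
    SaemSettings,
    eta_shrinkage,
    fit_saem,
    stepwise_covariates,
)


def small_cohort(pop, n=24, seed=5, missing=0.0):
    n_tdm = n - 6
    counts = (n_tdm - 2, 1, 1, 0, 0, 0) if n_tdm >= 4 else (n_tdm, 0, 0, 0, 0, 0)
    design = CohortDesign(
        seed=seed, n_tdm_subjects=n_tdm, tdm_visit_counts=counts,
        n_rich_subjects=6, covariate_missing_rate=missing)
    return generate_cohort(design, pop)


class TestFitSaem:
    def test_noise_free_fixed_effects_within_one_percent(self):
        gen = PopulationParameters(ka_pop=0.976, v_pop=22.3, cl_pop=0.458,
                                   err_add=0.01)
        design = CohortDesign(seed=6, n_tdm_subjects=8,
                              tdm_visit_counts=(4, 2, 2, 0, 0, 0),
                              n_rich_subjects=10, covariate_missing_rate=0.0)
        cohort = generate_cohort(design, gen)
        init = PopulationParameters(ka_pop=1.8, v_pop=40.0, cl_pop=0.8,
                                    omega_ka=0.2, omega_v=0.2, omega_cl=0.2,
                                    err_add=0.1, err_prop=0.05)
        fit = fit_saem(cohort, init,
                       SaemSettings(seed=3, n_explore=500, n_smooth=500,
                                    estimate_iov=False, compute_ofv=False,
                                    compute_rse=False))
        est = fit.estimates
        assert abs(est.ka_pop - 0.976) / 0.976 < 0.01
        assert abs(est.v_pop - 22.3) / 22.3 < 0.01
        assert abs(est.cl_pop - 0.458) / 0.458 < 0.01

    def test_same_seed_reproduces_trace_exactly(self, reference_pop):
        cohort = small_cohort(reference_pop, n=12, seed=8)
        init = PopulationParameters(ka_pop=1.5, v_pop=30.0, cl_pop=0.6,
                                    omega_ka=0.3, omega_v=0.3, omega_cl=0.3,
                                    gamma_v=0.1, gamma_cl=0.1,
                                    err_add=1.0, err_prop=0.3)
        settings = SaemSettings(seed=4, n_explore=50, n_smooth=30,
                                compute_ofv=False, compute_rse=False)
        fit1 = fit_saem(cohort, init, settings)
        fit2 = fit_saem(cohort, init, settings)
        for lab, arr in fit1.convergence_trace.items():
            np.testing.assert_array_equal(arr, fit2.convergence_trace[lab])

    def test_aic_identity(self, recovery_fit):
        # AIC = OFV + 2 * n_params, exactly, even when OFV was not computed
        assert recovery_fit.aic == recovery_fit.ofv + 2 * recovery_fit.n_params \
            or (math.isnan(recovery_fit.ofv) and math.isnan(recovery_fit.aic))

    def test_degenerate_data_rejected(self, reference_pop):
        cohort = small_cohort(reference_pop, n=12, seed=8)
        for s in cohort.subjects:
            s.obs_conc = np.zeros_like(s.obs_conc)
            s.obs_blq = np.ones_like(s.obs_blq)
        with pytest.raises(ValueError):
            fit_saem(cohort, reference_pop, SaemSettings(seed=1))


class TestRecovery:
    """Parameter recovery on the default 73-subject design (shared fit)."""

    def test_clearance_recovered(self, recovery_fit):
        assert abs(recovery_fit.estimates.cl_pop - 0.458) / 0.458 < 0.15

    def test_volume_recovered(self, recovery_fit):
        assert abs(recovery_fit.estimates.v_pop - 22.3) / 22.3 < 0.15

    def test_absorption_recovered(self, recovery_fit):
        assert abs(recovery_fit.estimates.ka_pop - 0.976) / 0.976 < 0.20

    def test_covariate_exponent_recovered(self, recovery_fit):
        assert abs(recovery_fit.estimates.beta_v_asat + 0.838) / 0.838 < 0.30

    def test_iiv_on_volume_recovered(self, recovery_fit):
        assert abs(100 * recovery_fit.estimates.omega_v - 24.8) / 24.8 < 0.30

    def test_rse_reported_for_every_parameter(self, recovery_fit):
        for lab in ("ka_pop", "v_pop", "cl_pop", "beta_v_ASAT"):
            assert np.isfinite(recovery_fit.rse[lab])
            assert 0 < recovery_fit.rse[lab] < 100

    def test_rich_design_keeps_clearance_shrinkage_low(self, recovery_fit):
        # clearance is the best-informed parameter in this design
        assert recovery_fit.shrinkage["cl"] < 30.0


class TestShrinkage:
    def _fit_with_ebes(self, etas, omega):
        fit = type("F", (), {})()
        fit.ebe = {f"S{i}": RandomEffects(eta_cl=e) for i, e in enumerate(etas)}
        return fit

    def test_ebes_at_full_spread_give_zero(self):
        rng = np.random.default_rng(0)
        etas = rng.normal(0, 0.3, 400)
        etas = (etas - etas.mean()) / etas.std() * 0.3  # exact SD 0.3
        fit = self._fit_with_ebes(etas, 0.3)
        pop = PopulationParameters(ka_pop=1, v_pop=20, cl_pop=0.5,
                                   omega_cl=0.3)
        out = eta_shrinkage(fit, pop)
        assert out["cl"] == pytest.approx(0.0, abs=1e-9)

    def test_collapsed_ebes_give_hundred(self):
        fit = self._fit_with_ebes(np.zeros(50), 0.3)
        pop = PopulationParameters(ka_pop=1, v_pop=20, cl_pop=0.5,
                                   omega_cl=0.3)
        assert eta_shrinkage(fit, pop)["cl"] == pytest.approx(100.0)

    def test_zero_omega_reported_not_applicable(self):
        fit = self._fit_with_ebes(np.zeros(10), 0.0)
        pop = PopulationParameters(ka_pop=1, v_pop=20, cl_pop=0.5)
        assert math.isnan(eta_shrinkage(fit, pop)["cl"])


class TestLikelihood:
    def _one_obs_subject(self, pop, y=30.0, t=6.0):
        reg = DoseRegimen(dose=800.0, tau=24.0,
                          n_doses_before_obs=SS_N_DOSES, occasion="V1")
        return Subject(
            id="S1", arm="tdm", regimens={"V1": reg},
            occasion_start={"V1": 672.0},
            covariates={"ASAT": {"V1": 36.5}},
            obs_occ=["V1"], obs_time=np.array([t]),
            obs_conc=np.array([y]), obs_blq=np.array([False]))

    def test_zero_variance_matches_closed_form_gaussian(self, reference_pop):
        pop = PopulationParameters(ka_pop=0.976, v_pop=22.3, cl_pop=0.458,
                                   err_add=2.0, err_prop=0.1)
        s = self._one_obs_subject(pop)
        cohort = Cohort(subjects=[s])
        res = log_likelihood_is(cohort, pop, mc_size=1000, seed=3)
        ip = apply_covariates(pop, 36.5, RandomEffects(), "V1")
        f = concentration_steady_state(ip, s.regimens["V1"], 6.0)
        sd = residual_sd(f, pop)
        exact = -2.0 * stats.norm.logpdf(30.0, loc=f, scale=sd)
        assert res.ofv == pytest.approx(exact, abs=1e-6)

    def test_single_random_effect_matches_quadrature_oracle(self):
        pop = PopulationParameters(ka_pop=0.976, v_pop=22.3, cl_pop=0.458,
                                   omega_cl=0.3, err_add=2.0, err_prop=0.1)
        s = self._one_obs_subject(pop, y=25.0, t=24.0)
        cohort = Cohort(subjects=[s])
        res = log_likelihood_is(cohort, pop, mc_size=20000, seed=3)

        def integrand(eta):
            re = RandomEffects(eta_cl=eta)
            ip = apply_covariates(pop, 36.5, re, "V1")
            f = concentration_steady_state(ip, s.regimens["V1"], 24.0)
            sd = residual_sd(f, pop)
            return (stats.norm.pdf(25.0, loc=f, scale=sd)
                    * stats.norm.pdf(eta, scale=0.3))

        lik, _ = integrate.quad(integrand, -3.0, 3.0, epsabs=1e-12)
        exact = -2.0 * math.log(lik)
        assert abs(res.ofv - exact) <= max(3.0 * res.se, 1e-3)

    def test_invariant_to_doubling_monte_carlo_size(self, reference_pop):
        cohort = small_cohort(reference_pop, n=10, seed=12)
        a = log_likelihood_is(cohort, reference_pop, mc_size=2000, seed=5)
        b = log_likelihood_is(cohort, reference_pop, mc_size=4000, seed=6)
        assert abs(a.ofv - b.ofv) <= 3.0 * math.sqrt(a.se ** 2 + b.se ** 2)

    def test_generating_model_beats_misspecified_model(self, reference_pop):
        cohort = small_cohort(reference_pop, n=30, seed=13)
        wrong = replace(reference_pop, cl_pop=2.0 * reference_pop.cl_pop)
        good = log_likelihood_is(cohort, reference_pop, mc_size=2000, seed=7)
        bad = log_likelihood_is(cohort, wrong, mc_size=2000, seed=7)
        assert good.ofv < bad.ofv

    def test_tiny_monte_carlo_size_rejected(self, reference_pop):
        cohort = small_cohort(reference_pop, n=10, seed=12)
        with pytest.raises(ValueError):
            log_likelihood_is(cohort, reference_pop, mc_size=50)


class TestStepwise:
    def test_inclusion_thresholds_are_the_chi_square_cut(self):
        assert OFV_SIGNIFICANT_DROP == pytest.approx(
            stats.chi2.ppf(0.95, df=1), abs=0.005)
        assert AIC_SIGNIFICANT_DROP == 2.0

    def test_decision_arithmetic(self):
        # dOFV 5.0 with one extra parameter -> dAIC 3.0 -> accepted;
        # dOFV 3.0 -> below the chi-square cut -> rejected
        assert 5.0 >= OFV_SIGNIFICANT_DROP and 5.0 - 2.0 >= AIC_SIGNIFICANT_DROP
        assert 3.0 < OFV_SIGNIFICANT_DROP

    def test_asat_effect_selected_and_recovered(self, reference_pop,
                                                neutral_init):
        cohort = small_cohort(reference_pop, n=40, seed=14)
        settings = SaemSettings(seed=9, n_explore=250, n_smooth=150,
                                mc_size=2000, compute_rse=False)
        base = fit_saem(cohort, neutral_init, settings, covariates=[])
        candidates = [CovariateCandidate("v", "ASAT", "power"),
                      CovariateCandidate("cl", "SEX", "categorical")]
        final, log = stepwise_covariates(cohort, base, candidates, settings)
        accepted = [e for e in log if e["status"] == "accepted"]
        assert accepted and accepted[0]["candidate"].covariate == "ASAT"
        assert abs(final.estimates.beta_v_asat + 0.838) / 0.838 < 0.5
        tested = {e["candidate"].covariate for e in log}
        assert tested == {"ASAT", "SEX"}
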