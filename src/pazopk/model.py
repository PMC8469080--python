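"""One-compartment oral-absorption PK model with lognormal random effects.

The structural model is a single central compartment with first-order
absorption (rate ``ka``) and first-order elimination (rate ``ke = Cl/V``),
parameterised in apparent clearance ``Cl/F`` and apparent volume ``V/F``
(oral bioavailability F is not identifiable from oral data alone).
Between-subject and between-occasion variability act multiplicatively
(lognormal): an individual's volume is

    V_i = V_pop * (ASAT_i / ASAT_ref) ** beta_V_ASAT * exp(eta_V + kappa_V[occ])

with aspartate transaminase (ASAT) as the single retained covariate, and
clearance and absorption follow the same exponential random-effect form.
The observation model is additive Gaussian with a combined residual
standard deviation ``sd = a + b * f`` (combined-1 convention).

All concentrations are mg/L, times hours, doses mg, volumes L and
clearances L/h throughout the package.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KA_KE_SWITCH_TOL",
    "STEADY_STATE_DOSES",
    "PopulationParameters",
    "RandomEffects",
    "IndividualParameters",
    "DoseRegimen",
    "apply_covariates",
    "concentration_single_dose",
    "concentration_steady_state",
    "predict_concentration",
    "predict_conc_arrays",
    "auc_from_clearance",
    "residual_sd",
    "typical_tmax",
]

# Relative |ka - ke| / ke below which the analytic ka == ke limit form is
# used.  Avoids catastrophic cancellation in ka/(ka-ke) while keeping the
# curve continuous well below test tolerances.
KA_KE_SWITCH_TOL = 1e-8

# Number of administrations after which a once-daily regimen is treated as
# at steady state (plasma levels plateau within 7-8 days of daily dosing).
STEADY_STATE_DOSES = 8


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


def _require_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, covariate coefficient, variability and error terms.

    ``omega_*`` are inter-individual (IIV) and ``gamma_*`` inter-occasion
    (IOV) standard deviations on the log scale; zero means the effect is
    absent.  ``err_add`` (mg/L) and ``err_prop`` (unitless) parameterise
    the combined residual error.
    """

    ka_pop: float
    v_pop: float
    cl_pop: float
    beta_v_asat: float = 0.0
    asat_ref: float = 36.5
    omega_ka: float = 0.0
    omega_v: float = 0.0
    omega_cl: float = 0.0
    gamma_v: float = 0.0
    gamma_cl: float = 0.0
    err_add: float = 0.0
    err_prop: float = 0.0
    error_model: str = "combined1"

    def __post_init__(self) -> None:
        for name in ("ka_pop", "v_pop", "cl_pop", "asat_ref"):
            _require_positive(name, getattr(self, name))
        for name in ("omega_ka", "omega_v", "omega_cl", "gamma_v",
                     "gamma_cl", "err_add", "err_prop"):
            _require_nonneg(name, getattr(self, name))
        if self.error_model not in ("combined1", "combined2"):
            raise ValueError(f"unknown error model {self.error_model!r}")

    @classmethod
    def reference(cls) -> "PopulationParameters":
        """The final published estimates, completed with the package's
        documented fixture assumptions for the terms the publication does
        not print (residual coefficients, omega_ka/omega_cl, IOV)."""
        return cls(
            ka_pop=0.976,
            v_pop=22.3,
            cl_pop=0.458,
            beta_v_asat=-0.838,
            asat_ref=36.5,
            omega_ka=0.30,
            omega_v=0.248,
            omega_cl=0.30,
            gamma_v=0.15,
            gamma_cl=0.15,
            err_add=1.0,
            err_prop=0.20,
        )


@dataclass
class RandomEffects:
    """Per-subject (eta) and per-occasion (kappa) log-scale deviations.

    An empty kappa dict means "no occasion-level variability"; a non-empty
    dict must contain every occasion that is looked up.
    """

    eta_ka: float = 0.0
    eta_v: float = 0.0
    eta_cl: float = 0.0
    kappa_v: dict = field(default_factory=dict)
    kappa_cl: dict = field(default_factory=dict)

    def kappa_for(self, which: str, occasion: str) -> float:
        d = self.kappa_v if which == "v" else self.kappa_cl
        if not d:
            return 0.0
        return d[occasion]  # KeyError if the occasion is absent


@dataclass(frozen=True)
class IndividualParameters:
    """Realised individual parameters; ``ke`` is derived as Cl/V."""

    ka: float
    v: float
    cl: float
    ke: float

    def __post_init__(self) -> None:
        for name in ("ka", "v", "cl", "ke"):
            _require_positive(name, getattr(self, name))
        if abs(self.ke - self.cl / self.v) > 1e-12 * self.ke:
            raise ValueError("ke must equal cl/v")

    @classmethod
    def from_rates(cls, ka: float, v: float, cl: float) -> "IndividualParameters":
        return cls(ka=ka, v=v, cl=cl, ke=cl / v)


@dataclass(frozen=True)
class DoseRegimen:
    """Once-daily oral dosing around an observation window.

    ``n_doses_before_obs`` counts administrations up to and including the
    one that opens the window: 1 means a first dose, values of
    ``STEADY_STATE_DOSES`` or more are treated as steady state.
    """

    dose: float
    tau: float = 24.0
    n_doses_before_obs: int = 1
    occasion: str = "occ1"

    def __post_init__(self) -> None:
        _require_positive("dose", self.dose)
        _require_positive("tau", self.tau)
        if self.n_doses_before_obs < 1:
            raise ValueError("n_doses_before_obs must be >= 1")

    @property
    def steady_state(self) -> bool:
        return self.n_doses_before_obs >= STEADY_STATE_DOSES

    @property
    def daily_dose(self) -> float:
        return self.dose * 24.0 / self.tau


def apply_covariates(pop: PopulationParameters, asat: float,
                     re: RandomEffects, occasion: str = "occ1") -> IndividualParameters:
    """Assemble an individual's parameters from the population model.

    V scales with the ASAT power term and exp(eta_V + kappa_V[occasion]);
    Cl with exp(eta_Cl + kappa_Cl[occasion]); ka with exp(eta_ka).
    """
    if not asat > 0:
        raise ValueError(f"asat must be strictly positive, got {asat!r}")
    v = (pop.v_pop
         * (asat / pop.asat_ref) ** pop.beta_v_asat
         * math.exp(re.eta_v + re.kappa_for("v", occasion)))
    cl = pop.cl_pop * math.exp(re.eta_cl + re.kappa_for("cl", occasion))
    ka = pop.ka_pop * math.exp(re.eta_ka)
    return IndividualParameters.from_rates(ka=ka, v=v, cl=cl)


def concentration_single_dose(ip: IndividualParameters, dose: float, t):
    """Concentration after a single oral dose at t hours post-dose."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    ka, ke, v = ip.ka, ip.ke, ip.v
    if abs(ka - ke) < KA_KE_SWITCH_TOL * ke:
        c = dose / v * ka * t_arr * np.exp(-ka * t_arr)
    else:
        c = (dose / v) * (ka / (ka - ke)) * (np.exp(-ke * t_arr) - np.exp(-ka * t_arr))
    c = np.maximum(c, 0.0)
    return c if t_arr.ndim else float(c)


def concentration_steady_state(ip: IndividualParameters, reg: DoseRegimen, t_after_dose):
    """Steady-state concentration profile over one dosing interval.

    Superposition of the single-dose solution over infinitely many prior
    doses spaced ``tau`` apart.  Over [0, tau] this is the steady-state
    interval profile (t=0 and t=tau both give the trough); t > tau gives
    the decay when the next administration is withheld until after
    sampling, the usual situation for a delayed trough draw.
    """
    t_arr = np.asarray(t_after_dose, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t_after_dose must be non-negative")
    ka, ke, v = ip.ka, ip.ke, ip.v
    tau = reg.tau
    if abs(ka - ke) < KA_KE_SWITCH_TOL * ke:
        e_tau = math.exp(-ka * tau)
        c = (reg.dose / v * ka * np.exp(-ka * t_arr)
             * (t_arr * (1.0 - e_tau) + tau * e_tau) / (1.0 - e_tau) ** 2)
    else:
        acc_ke = 1.0 - math.exp(-ke * tau)
        acc_ka = 1.0 - math.exp(-ka * tau)
        c = (reg.dose / v) * (ka / (ka - ke)) * (
            np.exp(-ke * t_arr) / acc_ke - np.exp(-ka * t_arr) / acc_ka)
    c = np.maximum(c, 0.0)
    return c if t_arr.ndim else float(c)


def predict_concentration(ip: IndividualParameters, reg: DoseRegimen, t_after_dose):
    """Concentration at t hours after the regimen's reference dose.

    Dispatches to the single-dose, finite-superposition or steady-state
    closed form based on how many doses precede the window.
    """
    n = reg.n_doses_before_obs
    if n == 1:
        return concentration_single_dose(ip, reg.dose, t_after_dose)
    if reg.steady_state:
        return concentration_steady_state(ip, reg, t_after_dose)
    # finite superposition: geometric sums of the two exponentials
    t_arr = np.asarray(t_after_dose, dtype=float)
    ka, ke, v = ip.ka, ip.ke, ip.v
    if abs(ka - ke) < KA_KE_SWITCH_TOL * ke:
        terms = [concentration_single_dose(ip, reg.dose, t_arr + j * reg.tau)
                 for j in range(n)]
        c = np.sum(terms, axis=0)
    else:
        g_ke = (1.0 - math.exp(-ke * n * reg.tau)) / (1.0 - math.exp(-ke * reg.tau))
        g_ka = (1.0 - math.exp(-ka * n * reg.tau)) / (1.0 - math.exp(-ka * reg.tau))
        c = (reg.dose / v) * (ka / (ka - ke)) * (
            np.exp(-ke * t_arr) * g_ke - np.exp(-ka * t_arr) * g_ka)
    c = np.maximum(c, 0.0)
    return c if t_arr.ndim else float(c)


def predict_conc_arrays(ka, v, cl, dose, tau, t, steady_state):
    """Vectorised concentration over parallel arrays of parameters.

    Used by the estimation machinery; every argument broadcasts
    element-wise and ``steady_state`` is a boolean mask selecting the
    steady-state closed form (otherwise single dose).
    """
    ka = np.asarray(ka, float)
    v = np.asarray(v, float)
    cl = np.asarray(cl, float)
    dose = np.asarray(dose, float)
    tau = np.asarray(tau, float)
    t = np.asarray(t, float)
    ss = np.asarray(steady_state, bool)

    with np.errstate(all="ignore"):  # extreme sampler proposals may overflow
        ke = cl / v
        near = np.abs(ka - ke) < KA_KE_SWITCH_TOL * ke
        ka_safe = np.where(near, ke * 2.0, ka)  # placeholder, masked out below

        coef = dose / v * ka_safe / (ka_safe - ke)
        e_ke_t = np.exp(-ke * t)
        e_ka_t = np.exp(-ka_safe * t)
        single = coef * (e_ke_t - e_ka_t)
        acc_ke = 1.0 - np.exp(-ke * tau)
        acc_ka = 1.0 - np.exp(-ka_safe * tau)
        sstate = coef * (e_ke_t / acc_ke - e_ka_t / acc_ka)

        if np.any(near):
            e_ka_lim = np.exp(-ka * t)
            single_lim = dose / v * ka * t * e_ka_lim
            e_tau = np.exp(-ka * tau)
            ss_lim = (dose / v * ka * e_ka_lim
                      * (t * (1.0 - e_tau) + tau * e_tau) / (1.0 - e_tau) ** 2)
            single = np.where(near, single_lim, single)
            sstate = np.where(near, ss_lim, sstate)

        return np.maximum(np.where(ss, sstate, single), 0.0)


def auc_from_clearance(dose_per_interval: float, cl: float) -> float:
    """AUC over one dosing interval at steady state: Dose / (Cl/F)."""
    if not cl > 0:
        raise ValueError(f"cl must be strictly positive, got {cl!r}")
    return dose_per_interval / cl


def residual_sd(pred, pop: PopulationParameters):
    """Standard deviation of an observation given its model prediction.

    combined1: sd = a + b*f  (default); combined2: sd = sqrt(a^2 + (b*f)^2).
    """
    pred_arr = np.asarray(pred, dtype=float)
    if np.any(pred_arr < 0):
        raise ValueError("pred must be non-negative")
    if pop.error_model == "combined2":
        sd = np.sqrt(pop.err_add ** 2 + (pop.err_prop * pred_arr) ** 2)
    else:
        sd = pop.err_add + pop.err_prop * pred_arr
    return sd if pred_arr.ndim else float(sd)


def typical_tmax(ip: IndividualParameters) -> float:
    """Time of the single-dose concentration peak."""
    ka, ke = ip.ka, ip.ke
    if abs(ka - ke) < KA_KE_SWITCH_TOL * ke:
        return 1.0 / ka
    return math.log(ka / ke) / (ka - ke)
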