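"""Virtual cohorts with the structure of the pazopanib study designs.

Two arms are emulated:

* a sparse therapeutic-drug-monitoring (TDM) arm: 58 patients sampled at
  trough (mean 24.6 h post-dose) over 1-6 monitoring visits, 126 samples
  in total;
* a rich trial arm: 15 patients with full 0-24 h profiles at
  0, 0.5, 1, 2, 4, 6, 8 and 24 h post-dose on cycle day 1 of cycles 1, 2
  and 4 (36 profiles, 280 samples; eight profiles carry 7 points).

The printed per-patient profile counts of the original study cannot be
reconciled exactly with its totals, so the default allocation preserves
the totals (36 profiles, 280 rich samples, 406 samples overall) and
yields exactly ten subjects with a complete 8-point steady-state profile
— the set used for leave-one-out validation.

Simulated concentrations keep their generating random effects in
``Subject.truth`` so recovery tests can compare estimates to ground
truth.  Ground truth is never used by any estimation code path.
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np

from .model import (
    DoseRegimen,
    PopulationParameters,
    RandomEffects,
    apply_covariates,
    predict_concentration,
    residual_sd,
)

__all__ = [
    "COVARIATE_NAMES",
    "LAB_COVARIATES",
    "FOOD_FASTED",
    "FOOD_FED",
    "FOOD_UNKNOWN",
    "SS_N_DOSES",
    "OCC_START_HOURS",
    "CohortDesign",
    "Subject",
    "Cohort",
    "generate_cohort",
    "simulate_observations",
    "impute_covariates",
    "censor_blq",
    "cohorts_equal",
]

COVARIATE_NAMES = ("ASAT", "ALAT", "ALB", "CREAT", "AGE", "SEX", "FOOD")
# laboratory covariates that may be missing and are subject to imputation
LAB_COVARIATES = ("ASAT", "ALAT", "ALB", "CREAT")

FOOD_FASTED, FOOD_FED, FOOD_UNKNOWN = 0.0, 1.0, 2.0

# canonical marker for "enough once-daily doses to be at steady state"
SS_N_DOSES = 10

# absolute start hour of each rich-arm occasion (day 1 of cycles 1, 2, 4;
# 28-day cycles) and spacing of TDM monitoring visits
OCC_START_HOURS = {"C1": 0.0, "C2": 672.0, "C4": 2016.0}
TDM_VISIT_SPACING_H = 672.0

RICH_SCHEDULE = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 24.0)


@dataclass(frozen=True)
class CohortDesign:
    """Study-design knobs; the defaults reproduce the published database."""

    n_tdm_subjects: int = 58
    # multiset of monitoring-visit counts: 23 subjects with 1 visit, ...;
    # sums to 126 samples with mean 2.17 visits per subject
    tdm_visit_counts: tuple = (23, 17, 9, 5, 2, 2)
    tdm_time_mean: float = 24.6
    tdm_time_sd: float = 2.0
    tdm_time_bounds: tuple = (20.0, 30.0)
    n_rich_subjects: int = 15
    rich_schedule: tuple = RICH_SCHEDULE
    dose_menu: tuple = (200.0, 400.0, 600.0, 800.0)
    # clinical-practice weights for the TDM arm (800 mg is the labelled
    # dose; reductions are common); the trial arm spreads evenly over the
    # four dose-escalation levels
    dose_probs: tuple = (0.10, 0.20, 0.20, 0.50)
    rich_dose_probs: tuple = (0.25, 0.25, 0.25, 0.25)
    asat_median: float = 36.5
    asat_log_sd: float = 0.45
    lloq: float = 1.0
    covariate_missing_rate: float = 0.10
    seed: int = 1

    def __post_init__(self) -> None:
        if len(self.tdm_visit_counts) != 6:
            raise ValueError("tdm_visit_counts must give counts for 1..6 visits")
        if sum(self.tdm_visit_counts) != self.n_tdm_subjects:
            raise ValueError("tdm_visit_counts must sum to n_tdm_subjects")
        if abs(sum(self.dose_probs) - 1.0) > 1e-9:
            raise ValueError("dose_probs must sum to 1")
        if abs(sum(self.rich_dose_probs) - 1.0) > 1e-9:
            raise ValueError("rich_dose_probs must sum to 1")
        if not 0 <= self.covariate_missing_rate < 1:
            raise ValueError("covariate_missing_rate must be in [0, 1)")

    @property
    def n_tdm_samples(self) -> int:
        return sum(k * n for k, n in zip(range(1, 7), self.tdm_visit_counts))


# rich-arm occasion allocation (subject index -> cycle labels) for the
# default 15-subject arm: 6x3 + 9x2 = 36 profiles
def _rich_occasions(i: int) -> tuple:
    return ("C1", "C2", "C4") if i < 6 else ("C1", "C2")


# profiles reduced to 7 points (the 0.5 h sample is dropped): cycle-2 of
# subjects 11-15 and cycle-1 of subjects 13-15 -> 8 profiles, so exactly
# subjects 1-10 keep a complete 8-point steady-state profile
_SEVEN_POINT = {(10, "C2"), (11, "C2"), (12, "C2"), (13, "C2"), (14, "C2"),
                (12, "C1"), (13, "C1"), (14, "C1")}


@dataclass
class Subject:
    id: str
    arm: str  # 'tdm' | 'rich'
    regimens: dict  # occasion -> DoseRegimen
    occasion_start: dict  # occasion -> absolute hour of its reference dose
    covariates: dict  # name -> {occasion: value}; NaN marks missing
    obs_occ: list  # occasion label per observation
    obs_time: np.ndarray  # hours after the occasion's reference dose
    obs_conc: np.ndarray
    obs_blq: np.ndarray
    truth: dict | None = None

    @property
    def n_obs(self) -> int:
        return len(self.obs_time)

    @property
    def occasions(self) -> list:
        return sorted(self.regimens, key=lambda o: self.occasion_start[o])

    def covariate_value(self, name: str) -> float:
        """Subject-level summary: median of non-missing occasion values."""
        vals = [v for v in self.covariates.get(name, {}).values()
                if not (isinstance(v, float) and math.isnan(v))]
        if not vals:
            return float("nan")
        return float(np.median(vals))

    def asat(self, default: float = 36.5) -> float:
        v = self.covariate_value("ASAT")
        return default if math.isnan(v) else v

    def obs_in(self, occasion: str) -> np.ndarray:
        return np.array([i for i, o in enumerate(self.obs_occ) if o == occasion],
                        dtype=int)

    def copy(self) -> "Subject":
        return copy.deepcopy(self)


@dataclass
class Cohort:
    subjects: list
    design: CohortDesign | None = None
    lloq: float = 1.0

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(s.n_obs for s in self.subjects)

    def subject(self, sid: str) -> Subject:
        for s in self.subjects:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def arm(self, which: str) -> list:
        return [s for s in self.subjects if s.arm == which]

    def copy(self) -> "Cohort":
        return copy.deepcopy(self)

    def covariate_median(self, name: str) -> float:
        vals = []
        for s in self.subjects:
            for v in s.covariates.get(name, {}).values():
                if not (isinstance(v, float) and math.isnan(v)):
                    vals.append(v)
        if not vals:
            raise ValueError(f"covariate {name!r} has no observed values in the cohort")
        return float(np.median(vals))


def _trunc_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    n = 0
    while n < size:
        draw = rng.normal(mean, sd, size=size)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(size - n, len(keep))
        out[n:n + take] = keep[:take]
        n += take
    return out


def _draw_covariates(rng, design: CohortDesign, n_tdm: int, n_rich: int) -> dict:
    """Draw subject-level covariates for the whole cohort (tdm then rich)."""
    n = n_tdm + n_rich
    cov = {}
    cov["ASAT"] = np.exp(rng.normal(math.log(design.asat_median),
                                    design.asat_log_sd, size=n))
    cov["ALAT"] = np.exp(rng.normal(math.log(30.0), 0.5, size=n))
    cov["ALB"] = np.clip(rng.normal(40.0, 5.0, size=n), 20.0, 55.0)
    cov["CREAT"] = np.exp(rng.normal(math.log(75.0), 0.3, size=n))
    age = _trunc_normal(rng, 55.0, 14.0, 18.0, 85.0, n)
    # three paediatric patients in the monitoring arm
    child_idx = rng.choice(n_tdm, size=min(3, n_tdm), replace=False)
    age[child_idx] = rng.uniform(8.0, 17.0, size=len(child_idx))
    cov["AGE"] = age
    cov["SEX"] = rng.integers(0, 2, size=n).astype(float)
    food = np.concatenate([
        np.full(52, FOOD_FASTED), np.full(15, FOOD_FED), np.full(6, FOOD_UNKNOWN)])
    if n != len(food):  # non-default sizes: keep the same proportions
        food = rng.choice([FOOD_FASTED, FOOD_FED, FOOD_UNKNOWN],
                          p=(52 / 73, 15 / 73, 6 / 73), size=n)
    else:
        food = rng.permutation(food)
    cov["FOOD"] = food
    return cov


def generate_cohort(design: CohortDesign, pop: PopulationParameters) -> Cohort:
    """Simulate a full two-arm cohort; deterministic given ``design.seed``.

    Builds the sampling skeleton (visits, schedules, doses, covariates),
    simulates concentrations under ``pop`` with residual noise, injects
    missing covariate values, and flags observations below the LLOQ.
    """
    rng = np.random.default_rng(design.seed)
    n_tdm, n_rich = design.n_tdm_subjects, design.n_rich_subjects

    cov = _draw_covariates(rng, design, n_tdm, n_rich)
    doses = np.concatenate([
        rng.choice(design.dose_menu, p=design.dose_probs, size=n_tdm),
        rng.choice(design.dose_menu, p=design.rich_dose_probs, size=n_rich)])

    visit_counts = np.repeat(np.arange(1, 7), design.tdm_visit_counts)
    visit_counts = rng.permutation(visit_counts)

    subjects = []
    for i in range(n_tdm):
        occs = [f"V{j + 1}" for j in range(int(visit_counts[i]))]
        start = {o: (j + 1) * TDM_VISIT_SPACING_H for j, o in enumerate(occs)}
        regimens = {o: DoseRegimen(dose=float(doses[i]), tau=24.0,
                                   n_doses_before_obs=SS_N_DOSES, occasion=o)
                    for o in occs}
        times = _trunc_normal(rng, design.tdm_time_mean, design.tdm_time_sd,
                              *design.tdm_time_bounds, size=len(occs))
        covariates = {name: {o: float(cov[name][i]) for o in occs}
                      for name in COVARIATE_NAMES}
        subjects.append(Subject(
            id=f"T{i + 1:02d}", arm="tdm", regimens=regimens,
            occasion_start=start, covariates=covariates,
            obs_occ=list(occs), obs_time=np.asarray(times, float),
            obs_conc=np.zeros(len(occs)), obs_blq=np.zeros(len(occs), bool)))

    for i in range(n_rich):
        occs = list(_rich_occasions(i))
        start = {o: OCC_START_HOURS[o] for o in occs}
        regimens = {o: DoseRegimen(dose=float(doses[n_tdm + i]), tau=24.0,
                                   n_doses_before_obs=1 if o == "C1" else SS_N_DOSES,
                                   occasion=o)
                    for o in occs}
        obs_occ, obs_time = [], []
        for o in occs:
            sched = [t for t in design.rich_schedule
                     if not ((i, o) in _SEVEN_POINT and t == 0.5)]
            obs_occ.extend([o] * len(sched))
            obs_time.extend(sched)
        covariates = {name: {o: float(cov[name][n_tdm + i]) for o in occs}
                      for name in COVARIATE_NAMES}
        subjects.append(Subject(
            id=f"R{i + 1:02d}", arm="rich", regimens=regimens,
            occasion_start=start, covariates=covariates,
            obs_occ=obs_occ, obs_time=np.asarray(obs_time, float),
            obs_conc=np.zeros(len(obs_occ)), obs_blq=np.zeros(len(obs_occ), bool)))

    cohort = Cohort(subjects=subjects, design=design, lloq=design.lloq)
    simulate_observations(cohort, pop, rng, store=True)

    # inject missing lab values after simulation so ground truth used the
    # actual covariate draw
    if design.covariate_missing_rate > 0:
        for s in cohort.subjects:
            for name in LAB_COVARIATES:
                for o in list(s.covariates[name]):
                    if rng.random() < design.covariate_missing_rate:
                        s.covariates[name][o] = float("nan")

    censor_blq(cohort, design.lloq)
    return cohort


def simulate_observations(cohort: Cohort, pop: PopulationParameters, rng,
                          store: bool = False) -> list:
    """Draw fresh random effects and residual noise on the cohort design.

    Returns one concentration array per subject, aligned with the
    subject's observation records.  With ``store=True`` the values (and
    the generating ground truth) are written back onto the cohort — the
    generator's path; diagnostics call it with ``store=False`` to obtain
    simulation replicates.
    """
    out = []
    for s in cohort.subjects:
        eta = RandomEffects(
            eta_ka=rng.normal(0.0, pop.omega_ka),
            eta_v=rng.normal(0.0, pop.omega_v),
            eta_cl=rng.normal(0.0, pop.omega_cl),
            kappa_v={o: rng.normal(0.0, pop.gamma_v) for o in s.occasions},
            kappa_cl={o: rng.normal(0.0, pop.gamma_cl) for o in s.occasions},
        )
        asat = s.asat(default=pop.asat_ref)
        ip_by_occ = {o: apply_covariates(pop, asat, eta, o) for o in s.occasions}
        f = np.empty(s.n_obs)
        for j, (o, t) in enumerate(zip(s.obs_occ, s.obs_time)):
            f[j] = predict_concentration(ip_by_occ[o], s.regimens[o], t)
        eps = rng.standard_normal(s.n_obs)
        y = f + residual_sd(f, pop) * eps
        # a sample with no drug reads blank, not Gaussian noise around
        # zero: pre-first-dose draws stay at zero (always below the LLOQ)
        y[f == 0.0] = 0.0
        out.append(y)
        if store:
            s.obs_conc = y
            s.truth = {
                "eta": eta,
                "ip": ip_by_occ,
                "pred": f,
                "auc": {o: s.regimens[o].daily_dose / ip_by_occ[o].cl
                        for o in s.occasions},
            }
    return out


def impute_covariates(cohort: Cohort) -> Cohort:
    """Fill missing covariate values; returns a modified copy.

    A patient's missing value is replaced by that patient's median over
    their non-missing values; if the patient has none, the cohort-wide
    median is used.  Raises if a covariate is entirely missing.
    """
    new = cohort.copy()
    names = set()
    for s in new.subjects:
        names.update(s.covariates)
    for name in sorted(names):
        pool = [v for s in new.subjects
                for v in s.covariates.get(name, {}).values()
                if not (isinstance(v, float) and math.isnan(v))]
        if not pool:
            raise ValueError(
                f"covariate {name!r} is missing for every subject; cannot impute")
        cohort_median = float(np.median(pool))
        for s in new.subjects:
            occs = s.covariates.get(name, {})
            own = [v for v in occs.values()
                   if not (isinstance(v, float) and math.isnan(v))]
            fill = float(np.median(own)) if own else cohort_median
            for o, v in occs.items():
                if isinstance(v, float) and math.isnan(v):
                    occs[o] = fill
    return new


def censor_blq(cohort: Cohort, lloq: float) -> Cohort:
    """Flag observations below the lower limit of quantification.

    The boundary value (== lloq) is kept; flagged records are excluded
    from fitting but retained in the dataset.  Mutates and returns the
    cohort.
    """
    if lloq < 0:
        raise ValueError("lloq must be non-negative")
    for s in cohort.subjects:
        s.obs_blq = np.asarray(s.obs_conc < lloq, bool)
    cohort.lloq = lloq
    return cohort


def _cov_equal(a: dict, b: dict) -> bool:
    if set(a) != set(b):
        return False
    for k in a:
        if set(a[k]) != set(b[k]):
            return False
        for o in a[k]:
            va, vb = a[k][o], b[k][o]
            na = isinstance(va, float) and math.isnan(va)
            nb = isinstance(vb, float) and math.isnan(vb)
            if na != nb or (not na and va != vb):
                return False
    return True


def cohorts_equal(a: Cohort, b: Cohort, include_truth: bool = False) -> bool:
    """Field-by-field equality of observable cohort content."""
    if a.n_subjects != b.n_subjects:
        return False
    for sa, sb in zip(a.subjects, b.subjects):
        if (sa.id, sa.arm) != (sb.id, sb.arm):
            return False
        if sa.occasions != sb.occasions:
            return False
        for o in sa.occasions:
            ra, rb = sa.regimens[o], sb.regimens[o]
            if (ra.dose, ra.tau, ra.n_doses_before_obs) != \
               (rb.dose, rb.tau, rb.n_doses_before_obs):
                return False
            if sa.occasion_start[o] != sb.occasion_start[o]:
                return False
        if sa.obs_occ != sb.obs_occ:
            return False
        if not (np.array_equal(sa.obs_time, sb.obs_time)
                and np.array_equal(sa.obs_conc, sb.obs_conc)
                and np.array_equal(sa.obs_blq, sb.obs_blq)):
            return False
        if not _cov_equal(sa.covariates, sb.covariates):
            return False
        if include_truth and (sa.truth is None) != (sb.truth is None):
            return False
    return True
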