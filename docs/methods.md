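# Methods

This note documents the models, algorithms, numerical choices and
limitations of `pazopk`, in the spirit of the methods sections that
accompany estimation libraries.

## Structural and statistical model

Disposition is a single compartment with first-order oral absorption
(rate `ka`, h⁻¹) and first-order elimination (`ke = Cl/V`), in apparent
parameterisation (`V/F`, `Cl/F`) because oral bioavailability F is not
identifiable from oral data. Closed forms are used throughout:

* single dose: `C(t) = D/V · ka/(ka−ke) · (e^(−ke t) − e^(−ka t))`;
* steady state (once daily, interval τ): the superposed geometric sum,
  `C_ss(t) = D/V · ka/(ka−ke) · (e^(−ke t)/(1−e^(−ke τ)) − e^(−ka t)/(1−e^(−ka τ)))`.
  The expression is also evaluated for `t > τ`, which corresponds to a
  delayed trough drawn before the next (withheld) dose — routine in TDM
  practice, where the mean sampling time is 24.6 h on a 24 h interval;
* a finite-superposition form covers regimens between the first dose
  and steady state (≥ 8 daily doses is treated as steady state,
  consistent with the drug reaching plateau within 7–8 days).

When `|ka − ke| < 10⁻⁸·ke` the code switches to the analytic limits
(`D/V · ka t e^(−ka t)` and its steady-state analogue) to avoid
catastrophic cancellation; continuity across the switch is covered by
tests.

Random effects are lognormal. Inter-individual deviations η apply to
`ka`, `V/F`, `Cl/F`; inter-occasion deviations κ apply to `V/F` and
`Cl/F` only (absorption occasion-to-occasion variation is absorbed by
the residual). ASAT enters `V/F` as a power of the ratio to its
reference (36.5 UI·L⁻¹). Residual error is "combined-1",
`sd = a + b·f`; the quadratic "combined-2" form is available through
`PopulationParameters.error_model`. Combined-1 was chosen as the
default convention of mainstream estimation software when a study description
names only "a combined model".

### Reference parameter set

`PopulationParameters.reference()` carries the published fixed effects
(ka 0.976 h⁻¹, V/F 22.3 L, Cl/F 0.458 L·h⁻¹, β_ASAT −0.838) and the
published IIV of V/F after covariate inclusion (24.8%, stored as the
log-scale SD 0.248; the package reports %CV as 100·ω throughout).
The remaining variability and error terms are not printed in the
published account and are fixture assumptions, stated once here:
ω_ka = ω_Cl = 0.30, γ_V = γ_Cl = 0.15, a = 1.0 mg·L⁻¹ (the scale of
the assay's quantification limit), b = 0.20. They are defaults, not
estimates.

## Synthetic cohorts

Real patient data are not deposited, so `generate_cohort` emulates the
two study arms:

* **TDM arm** — 58 patients, trough samples at monitoring visits spaced
  28 days. The visit-count multiset is fixed (23×1, 17×2, 9×3, 5×4,
  2×5, 2×6), which guarantees the printed total of 126 samples and the
  mean of 2.17 visits; a random draw could not honour the total.
  Sampling times are Normal(24.6, 2.0²) h truncated to [20, 30].
  Doses are drawn from {200, 400, 600, 800} mg with weights
  0.10/0.20/0.20/0.50 (800 mg is the labelled dose; reductions are
  common in practice).
* **Rich arm** — 15 patients profiled at 0, 0.5, 1, 2, 4, 6, 8, 24 h
  after dosing on day 1 of cycles 1 (first dose), 2 and 4 (steady
  state). Six patients carry all three cycles and nine carry cycles
  1–2 (36 profiles); eight profiles lose the 0.5 h point, giving
  28 eight-point and 8 seven-point profiles (280 samples) and exactly
  ten patients with a complete 8-point steady-state profile — the
  leave-one-out validation set. The printed per-patient counts of the
  original study cannot be reconciled exactly with its totals; this allocation
  preserves all three totals (36 profiles, 280 rich samples, 406
  overall). Doses spread uniformly over the four escalation levels.

Covariates: ASAT lognormal with median 36.5 and log-SD 0.45; ALAT,
albumin, creatinine, age, sex and food status are generated with
plausible clinical distributions, carried through the dataset, but
exert no effect under the final model. Food status splits 52/15/6
fasted/fed/unknown across the 73 subjects. Laboratory covariates are
knocked out missing-at-random at 10% by default to exercise the
imputation rule (patient median first, cohort median as fallback).

Observations are simulated with combined residual noise and flagged
BLQ below the 1 mg·L⁻¹ quantification limit; BLQ records are excluded
from fitting (M1-style) but retained in datasets. Pre-first-dose
samples contain no drug and are simulated as true blanks (always BLQ)
rather than Gaussian noise around zero — an assay cannot report
phantom drug.

What the generator does **not** emulate: co-medication effects
(notably enzyme induction, which likely depressed exposure in the real
trial arm — about 70% of the study's steady-state samples sat below
the efficacy trough, more than the published parameters alone
reproduce), food effect on bioavailability, dose changes within a
patient, adherence gaps, and assay batch effects. Passing tests on
these cohorts therefore demonstrate the machinery under the model's
own assumptions, not robustness to real-world misspecification.

## SAEM estimation

The E-step samples each subject's latents with Markov-chain Monte
Carlo. Latents are the subject-level log-parameter locations φ and,
for V/F and Cl/F, occasion-level values ψ ~ N(φ, γ²). This two-level
parameterisation makes the complete-data model an exponential family:
the M-step for fixed effects and covariate coefficients is a linear
regression of the sampled φ on the covariate design, and ω², γ² are
averaged squared deviations. φ_V and φ_Cl have conjugate Gaussian full
conditionals (exact Gibbs); φ_ka and the ψ values use random-walk
Metropolis with per-coordinate scales adapted toward ~0.35 acceptance
during exploration. The combined-error pair (a, b) has no closed-form
update and is obtained by a bounded quasi-Newton solve on smoothed
(prediction, squared-residual) statistics.

Schedule: 500 exploration iterations (step 1, simulated-annealing
floors `var ← max(var̂, 0.95·var)` to prevent premature variance
collapse) followed by 3000 smoothing iterations with step `1/k^0.7`,
five MH transitions per iteration. The long smoothing phase matters:
with a few hundred iterations the sampler's Monte-Carlo error on
weakly identified directions (the ASAT exponent, the ω_V/γ_V split)
is as large as the statistical standard error; a few thousand
smoothing iterations bring replicate fits from different sampler seeds
into close agreement. A full fit of the 73-subject design takes
~15 s on one CPU.

The observed-data objective (OFV = −2 log L) is computed by
importance sampling: per subject, a Student-t proposal (df 5 by
default) centred at the conditional mode with Laplace covariance from
a finite-difference Hessian; Monte Carlo size 10,000 by default, with
the IS standard error reported. AIC = OFV + 2·n_params exactly.
Relative standard errors come from the empirical Fisher information
assembled from stochastically averaged per-subject complete-data
scores over the smoothing phase; the subject bootstrap is the fallback
when that matrix is ill-conditioned.

Forward stepwise covariate selection refits each candidate (power form
on the ratio to the cohort median for continuous covariates,
multiplicative indicator for categorical ones, `log(dose/800)` for
dose) and accepts the best candidate only when the OFV drops by at
least 3.84 (χ²₁, p = 0.05) **and** the AIC by at least 2 — both cuts
enforced jointly, since the study applies both descriptions.

### Known identifiability limits

With 15 rich patients and mostly single-visit sparse patients, the
partition of V/F variability between ω_V and γ_V is likelihood-flat:
re-splitting a fitted total variance at the generating ratio changes
the OFV by ~0.1 (within IS noise). Replicate simulations therefore
scatter the reported ω_V by tens of percent around the generating
value even when the fit is at a true MLE (verified by comparing IS-OFV
at fitted versus generating parameters). ka is informed almost
entirely by the 15 rich profiles' early samples and carries ~10–15%
replicate-level spread. M1-style BLQ exclusion biases the additive
error term upward by ~20–40% because it truncates the low-concentration
noise tail; this is a property of the exclusion rule, not a defect of
the optimizer.

## Individual (MAP) estimation

`map_estimate` minimises

    Σ_obs [ (y − f)²/sd(f)² + 2·log sd(f) ] + zᵀ Ω⁻¹ z

over the subject's IIV deviations plus the sampled occasions' IOV
deviations (Ω block-diagonal from ω², γ²). L-BFGS-B with five starts
(origin plus four jittered) guards against the shallow ridges a single
observation induces; coordinates whose prior SD is ≤ 10⁻⁶ are pinned
at zero. The reported AUC is the sampled occasion's daily dose divided
by the occasion-level Cl/F — so `AUC·Cl = dose` holds exactly. TDM
samples on a stable regimen of ≥ 8 days are evaluated against the
steady-state curve; cycle-1 day-1 profiles use the single-dose curve.
A single sample within 1 h of the subject's typical absorption peak is
flagged `near-cmax` (clearance is least identifiable there).

## Non-compartmental reference

`auc_linuplogdown` applies the linear trapezoid on rising or
zero-touching segments and the log trapezoid on strictly decreasing
positive segments (exact for mono-exponential decline).
`lambda_z_bestfit` scans every terminal window of ≥ 3 points strictly
after Cmax, maximises adjusted R² with ties (within 10⁻⁴) resolved
toward the wider window. Steady-state profiles need no extrapolation
(`Cl = dose/AUC_0–τ`); single-dose profiles extrapolate to infinity
with λ_z, falling back to the observed span with an explicit flag when
no usable terminal phase exists. A pre-dose sample exceeding the 24 h
sample is flagged inconsistent, never corrected.

## Diagnostics

* **VPC**: simulate the fitted model on the observed design (default
  1000 replicates), bin times by 1-D least-squares (Lloyd) clustering
  with k = 8 (the binning criterion is named by the study, the count
  is ours), no stratification; report observed 10th/50th/90th
  percentiles against their 90% simulation bands.
* **NPDE**: per subject, decorrelate observed and simulated vectors
  with the Cholesky factor of the simulated covariance
  (ridge-stabilised when singular), rank, and map through the normal
  quantile function; standard normal under the correct model.
* **Bootstrap**: resample subjects with replacement, refit each
  replicate with a shortened schedule (100 + 50 iterations) so that
  100 replicates stay desk-scale; report per-parameter quartiles and
  whether the reference estimate lies within [Q1, Q3].
* **Leave-one-out**: for each of the ten complete steady-state
  profiles, refit the population model without that subject
  (shortened schedule, 150 + 100), estimate their Cl/F from each
  profile sample individually, convert to AUC, and compare with the
  NCA reference. The summary reports the mean absolute relative AUC
  deviation, the two-way agreement between (AUC < 750) and
  (observed trough < 20.5) over all sample-level decisions, and —
  as the original study counts it — the conditional rate of below-target AUC
  among below-criterion troughs. Note that 750 mg·h·L⁻¹ and
  20.5 mg·L⁻¹ are not ratio-consistent under the model's typical
  elimination rate (750 corresponds to a typical trough near
  24.7 mg·L⁻¹), so two-way agreement saturates below 100% even with a
  perfect estimator; the gap is a property of the threshold pair.

## Exposure decisions

"Positive" means adequate exposure throughout: condition positive when
C_trough ≥ 20.5 mg·L⁻¹ (20.0 available via configuration), test
positive when AUC ≥ threshold. The scan grid runs 250–1500 mg·h·L⁻¹
in 50 mg·h·L⁻¹ steps; the chosen threshold maximises Youden's J with
ties resolved toward the lower threshold. `classify_exposure` keeps
the boundary (AUC exactly at target) on the adequate side. The
cycle-to-cycle comparison is a paired Wilcoxon signed-rank test (the
source names "Wilcoxon–Mann–Whitney with paired samples"; the paired
reading is implemented), exact for ≤ 25 untied pairs, normal
approximation with continuity correction otherwise.

## Problem sizes

Defaults were chosen to keep a full analysis on one desktop CPU:
the SAEM fit ~7 s; IS likelihood at Monte Carlo size 10,000 ~20 s for
73 subjects; a 1000-replicate VPC ~20 s; the ten-fold leave-one-out
~25 s with the shortened fold schedule. The acceptance script
(`scripts/acceptance.py`) runs the complete set in roughly half a
minute.
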