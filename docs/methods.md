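# Methods

## Data model and estimand

The unit of analysis is a patient trajectory on a biannual grid
t = 0, 0.5, …, 4.0 years. Each visit carries an on-treatment flag A_t,
five time-varying clinical scores L_t (UPDRS-I/II-like, off-state motor
score, ADL, cognition), and time-fixed baseline covariates B (age, sex,
education, cardiovascular disease, disease duration). Treatment recorded at
a visit is assumed to cover the preceding half-year period (t − 0.5, t]:
initiation decisions are taken at a visit based on the state observed
there, and show up as A = 1 at the next visit. Treatment is monotone; any
patient with a 1 → 0 transition (a discontinuer) is excluded before
estimation, and unknown flags are resolved by last-observation-carried-
forward (interior gaps between two treated visits are forced to 1;
trajectories whose start time is undeterminable — unknown flags before the
first known value with a later treated visit — are excluded rather than
guessed). Duration within the 2-year window is D = 0.5 × #{treated visits
in (0, 2]}, so the four observable start categories (effective start at
0, 0.5, 1, 1.5 years) map to D = 2.0, 1.5, 1.0, 0.5.

The estimand is the slope β of the policy mean E[Y_h(d)] in d: the change
in the mean annual outcome at horizon h ∈ {2, 3, 4} years if every
patient's within-window treatment duration were increased by one year.
Analyses are restricted to patients on treatment at h, so the long-duration
symptomatic response is present in everyone compared. Missing outcomes are
handled complete-case by default, with an optional inverse-probability-of-
missingness weight from a logistic model on baseline covariates.

## Estimators

*Naive*: OLS of Y_h on D. *Baseline-adjusted*: OLS of Y_h on D and Y_0
(optionally missingness-weighted). Both are deliberately confounded
comparators.

*IPTW MSM*: at each decision visit t ∈ {0.5, 1.0, 1.5, 2.0}, initiation
among still-untreated patients is modeled by a logistic regression on the
previous visit's L and B — unpooled across visits. Stabilized weights
multiply num/den factors over decision visits up to and including
initiation (all four if never initiated): at initiation num = the marginal
per-visit initiation fraction (the intercept-only MLE), den = the fitted
conditional probability; otherwise the complements. Patients treated at the
baseline visit predate the decision window and receive weight 1. Fitted
probabilities are clipped to [1e-6, 1 − 1e-6]; clipping events, degenerate
visits (0% or 100% initiation, which contribute factor 1 with a warning)
and the effective sample size (Σw)²/Σw² are reported as positivity
diagnostics. The MSM E[Y_h(d)] = β₀ + β d is fit by weighted least squares
among starters; its HC0 sandwich standard error is a convenience only.

*Parametric g-formula*: at each visit t, each score in L_t is regressed on
(1, L_{t−0.5}, B, A_t), unpooled across time; the outcome model at h has
the same form but is fit on validly observed outcomes. For each policy
duration d ∈ {0.5, 1.0, 1.5, 2.0} (treatment from visit 2.5 − d onward),
n_mc = 100 covariate trajectories per patient are simulated forward from
baseline with Gaussian residual noise at the fitted per-(variable, time)
residual SDs; the policy mean is the average predicted outcome at h
(terminal noise is omitted — it has mean zero and only adds Monte Carlo
variance). β is the OLS slope of the four policy means on d. A
deterministic mode propagates conditional means without noise; because all
models are linear this reproduces the policy means exactly and is used for
the exactness checks. Covariates are updated simultaneously from the
previous visit (no within-step ordering), matching the first-order
structure of the treatment models. Rank-deficient designs (e.g. constant
columns in degenerate test panels) fall back to minimum-norm least squares
rather than failing; a design containing non-finite values raises an error
naming the time point.

*Enumeration oracle*: for finite-state toy processes with known transition
and initiation tables, policy means are computed exactly by summing over
all state paths. On processes whose transition means are additive in
(state, treatment) — so the linear models are saturated — the parametric
g-formula fit on a dataset enumerating every observational path with its
exact probability weight must match the oracle to numerical precision
(verified to 1e-8). All probabilities in the shipped toy are dyadic
rationals so path weights are exact in binary floating point.

*Bootstrap*: patients are resampled with replacement to the original size
(an m-out-of-n without-replacement mode exists behind a flag); the entire
pipeline — treatment models, weights, progression models — is refit per
replicate; the interval is point ± 2 bootstrap SDs. Replicate seeds are
spawned from the master seed, failures (degenerate resamples) are counted
and excluded, and more than 20% failures raises an error instead of
reporting an unreliable interval.

## Synthetic cohort generator

The generator emulates the structure the estimators assume, with a known
ground truth. A severity process S starts at N(21, 9²) (matching a de novo
cohort's off-state motor score) and worsens by drift = 1.0 point per
half-year untreated, with progression noise σ_p = 1.0 per period. The
treatment effect is additive on the *state*: −β/2 points per treated
half-year (default β = −1.5 per treatment-year, negative = benefit), so
the effect persists and E[Y(d+1)] − E[Y(d)] = β exactly at every horizon —
the closed-form ground truth. A config flag adds a purely symptomatic
additive offset to the measured motor score while on treatment; it shifts
all started policies equally at the annual assessments and leaves β
unchanged.

The off-state motor score *is* the severity index (identity map, no
independent measurement error); the four secondary scores are affine in S
plus Gaussian noise (σ_measure = 2.0, scaled per score). Initiation at each
visit among the untreated follows logistic(α₀ + α₁ z) with
z = (S − 21)/(3 × 9): the severity index is standardized to the cohort's
clinical range (≈3 SD), so with the defaults α₀ = −1.5, α₁ = 3 the
per-visit hazard stays within ≈(0.004, 0.8) across ±3 SD — strong
confounding *within* the positivity regime, which is a design requirement
for a generator meant to validate weighting estimators. These defaults give
≈60% of patients started by year 2 with most starts in the first year, and
duration support over all four categories. Making the decision depend on
the measured (not latent-noisy) score makes measured-covariate
exchangeability and the first-order Markov structure hold exactly, the
standard construction for MSM/g-formula simulation studies; real cohorts
offer no such guarantee, so passing recovery tests demonstrates estimator
correctness under the stated assumptions, not robustness to unmeasured
confounding or model misspecification.

Baseline covariates match a de novo PD cohort: age N(61.3, 9.7²), 67%
male, education N(15.6, 2.9²), cardiovascular disease 30%, disease
duration Exponential(mean 0.5 y). Treated patients receive a medication-
class label (levodopa 45% / dopamine agonist 16% / other 13% /
combination 26%) used only by the regimen filter. Outcome missingness
(default 20% of annual assessments, missing completely at random) clears
the outcome-availability flag at years 2–4 — emulating failed off-state
assessment criteria — while leaving the visit's covariate block intact;
visit-level covariate missingness and treatment-flag missingness are
separate toggles (defaults 0) feeding carry-forward and imputation. Nobody
is treated at the baseline visit (de novo cohort); the baseline-treated
weight path is exercised by constructed test panels.

## Problem sizes and numerical choices

Acceptance-level simulations use 100–200 replicate cohorts of n = 1000–5000
patients and 200 bootstrap repeats (scaled down from 1000 for the shipped
suite; the bootstrap-SE sanity check uses the full 1000). Observed behavior
at these sizes: IPTW and g-formula means within ±0.3 of the true −1.5
(typical replicate SDs ≈0.7 and ≈0.07 at n = 2000); under a null effect
with confounding the naive mean is strongly positive while both causal
estimators stay within ±0.2 of zero; ±2 SD bootstrap intervals cover the
truth at a rate consistent with ≈95%. Probability clipping at 1e-6;
logistic fits fall back to LBFGS with clipped predictions under separation
(with a warning); hypothesis-based property tests are derandomized.

## Known limitations

- The LOCF treatment-status imputation is a documented, swappable stand-in;
  cohort-specific imputation procedures may differ.
- The g-formula's first-order (previous-visit) conditioning is exactly
  correct for the generator but an approximation for processes with longer
  memory; at horizons 3–4 with outcome missingness, carried-forward annual
  covariates slightly attenuate the fitted progression models.
- Complete-case outcome handling assumes missingness at random given the
  model's covariates; only baseline covariates enter the missingness model.
- Binary endpoints (dyskinesias, motor fluctuations), dose adjustment,
  interaction/subgroup effects, and doubly robust estimators are out of
  scope; the levodopa-only analysis is supported as a row filter only.
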