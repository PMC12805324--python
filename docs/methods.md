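# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic-data generator's scope, and the design
choices made where the design was genuinely open.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Minute-level wear validation

A minute with an observed heart rate is wear.  A minute with missing HR is
eligible for gap filling only when it carries concurrent activity evidence —
steps > 0, METs > 1.0 or intensity code > 0 — in which case it receives the
arithmetic mean of the nearest observed-HR minute on each side.  Two
precision points the narrative rules leave open are fixed as follows:

* **Neighbour search** is bounded to the same calendar day and to a maximum
  distance of `max_fill_gap` minutes (default 60) on each side.  Unbounded
  interpolation across multi-hour gaps would fabricate wear where the device
  was plainly off.  Filled values never seed further fills.
* **Order of operations** is wear detection -> gap fill -> plausibility
  window -> flat-line exclusion -> day tally, so the plausibility window
  (strictly below 45 or strictly above 205 bpm is excluded; the bounds
  themselves are retained) also applies to filled values.  This is
  switchable (`exclude_filled`).

Flat-line runs are maximal sequences of timestamp-adjacent observed minutes
with identical HR; runs of `flatline_min_run` (default 11) or more minutes
are excluded in full.  Filled minutes are excluded from run detection — a
fill is constant by construction and would create artificial flat-lines — and
any missing minute or timestamp gap breaks a run.  A minute already excluded
by the plausibility window keeps that reason; since a run is value-uniform,
this matters only for runs that are implausible as a whole.

Statuses partition the stream (valid observed / valid filled / excluded /
nonwear), per-reason tallies partition the non-valid minutes, and the whole
stage is checked minute-for-minute against an independently written
explicit-loop oracle on randomized streams.

A valid wear day carries >= `valid_day_minutes` (1200) valid minutes; a
valid wear patient has >= `valid_patient_days` (7) valid days over all
available data.

## Daily features and phenotyping

MVPA is operationalized through the device's intensity codes 2–3, with
METs > 3.0 as the fallback when the code is absent; this reconciles the
device's native labels with the absolute > 3 MET definition of
moderate-to-vigorous activity.  Sedentary fraction is sedentary minutes over
valid wear minutes.  Resting HR comes from the device's daily export when
supplied, otherwise the minimum 30-minute rolling mean of the day's
effective HR — both paths are provided because either source is defensible.
Sleep sessions attach to the date of bed start; go-to-bed times are coded as
hours since the prior midnight (00:06 -> 24.1) so bedtimes spanning midnight
average correctly.  Group tables average within patient first, then across
patients, so patients with more wear days are not over-weighted.

The phenotype threshold converts the WHO guideline of 150 MVPA minutes per
week to 150/7 = 21.4 min/day (rounded half-up to one decimal).  "Reaching"
the threshold is read inclusively (>=); the boundary behaviour is
config-switchable and exercised by the sensitivity machinery.  The patient
mean is over valid wear days only — missing days carry no information and
the pipeline deliberately performs no imputation of whole days.

## PRO scoring

The symptom severity composite is frequency x intensity on 0–4 scales, the
only product form consistent with the documented 0–16 range.  Instrument
totals are plain sums over complete item sets (no prorating; any missing
item voids the total): PHQ-2 two items 0–3 with a clinical flag at >= 3,
GAD-7 seven items 0–3, PROMIS-29 domains four items 1–5.  Severity
categories use the conventional 1-SD / 2-SD T-score bands — acceptable/mild
below 60, moderate in [60, 70), significant at 70+ for higher-worse domains,
mirrored at 40 / 30 for the lower-worse domains (physical function, social
roles, cognition) — and are fully configurable because no single standard
set of cutoffs is universal.  Raw-to-T conversion tables are licensed
HealthMeasures content and are not shipped; a user-supplied lookup CSV is
accepted instead.  Change scores are pairwise within-subject differences
computed only when both waves are present.

## Cross-sectional statistics

`compare_groups` routes categorical outcomes to chi-squared on the
contingency table (no continuity correction by default — toggleable; with
correction the PHQ-2 example below lands near .14 rather than .085) and
continuous outcomes through per-group Shapiro–Wilk at alpha = .05: both
normal -> Student's t (equal variances), otherwise Wilcoxon rank-sum with an
exact p when both groups are below 25 and untied, else the tie-corrected
normal approximation.  Groups below n = 3 cannot be normality-tested and
fall back to Wilcoxon with a warning.

### Hawkins MCAR test

No installed package provides a missingness-mechanism test, so the
k-sample procedure is implemented from the primary sources.  Cases are
grouped by missingness pattern and compared for a common mean and covariance
under an EM-estimated multivariate normal model:

* **Mean component.**  Each pattern's observed sub-vector mean is compared
  against the EM mean via the classical chi-squared statistic
  (sum over patterns of n_j d_j' Sigma_oo^-1 d_j, df = sum p_j − p).
* **Covariance component.**  The data are completed by drawing missing
  entries from their conditional normal distribution (a proper draw, not
  conditional-mean imputation, which would deflate within-pattern variance
  and break calibration).  Within each pattern group of at least
  `min_cases` (default 6) cases, the per-case Hawkins F tail probabilities
  are Uniform(0,1) under homoscedastic normality; each group's uniformity
  is scored with a Cramér–von Mises test and group p-values are
  Fisher-combined.  Pooling all tail probabilities directly in one Fisher
  statistic is *not* done: the pooled covariance constrains the total
  distance, making the tail probabilities strongly negatively dependent and
  the pooled statistic severely conservative (this was measured, not
  assumed).

The overall p Fisher-combines the two components (chi-squared, 4 df).  The
test assumes approximate multivariate normality: heavily discrete bounded
instruments (e.g. PHQ-2 totals) can trigger rejections that reflect
non-normality rather than the missingness mechanism, which is worth keeping
in mind when reading per-instrument results.

## Longitudinal mixed-effects models

The core specification regresses a PRO score on time (0/1/2 in 3-month
units, or categorical wave labels), MVPA group, their interaction and the
patient's baseline score, with a patient random intercept, fitted by REML
(statsmodels MixedLM).  Three baseline-handling variants are shipped because
the right treatment of the baseline wave is genuinely open:

* **covariate + baseline rows** ("literal"): baseline observations appear as
  outcomes *and* the baseline score enters as a covariate.  At wave 0 the
  outcome then equals the covariate exactly, so the model can reproduce
  baseline rows with zero residual; the shared residual variance gets pulled
  down and Wald tests of the within-patient terms become anticonservative.
  This collinearity is a measurable defect (the simulation studies in the
  test suite quantify it), so the variant is provided and appears in the
  sensitivity grid but is not the estimation default.
* **ANCOVA** (baseline as covariate, follow-up waves only as outcomes): the
  standard baseline-adjusted formulation; unbiased but least efficient for
  the interaction here, because only the 3-to-6-month contrast identifies
  the slope difference.
* **growth** (all waves as outcomes, no baseline covariate): the default for
  interaction estimation and for the recovery harnesses.  It uses the full
  0–6-month span, is correctly specified for a random-intercept trajectory
  process, and its interaction test is the best calibrated of the three in
  the package's simulations.

Inference uses Wald t statistics with within/between degrees of freedom
(within-patient terms: observations − patients − within-term count;
between-patient terms: patients − between-term count), a close approximation
to Satterthwaite df for random-intercept designs of this shape, and Wald 95%
CIs.  Model comparison across fixed-effect sets refits with ML (REML
likelihoods are not comparable across mean structures) and reports AIC with
a guard that all candidates share one observation set.  An interaction
exceeding 3 T-score points in magnitude is annotated against the
conventional meaningful-change threshold for PROMIS scales.

Diagnostics: Shapiro–Wilk on conditional residuals (standard mixed-model
practice), and a White-type LM test regressing squared *marginal* residuals
on the marginal fitted values and their squares (n R² ~ chi-squared, 2 df).
Marginal residuals are used deliberately: predicted-random-effect shrinkage
couples conditional residuals to the fitted values even under a correct
model, which was measured to produce a badly oversized test; on marginal
residuals the test is mildly conservative under within-patient correlation
but retains full power against variance-proportional-to-mean alternatives.
Neither diagnostic triggers automatic refitting.

## Growth mixture model

Day-level series (time = days since each patient's own deployment) follow a
finite mixture of linear trajectories: class-specific intercept and slope,
one shared patient random-intercept variance and one shared residual
variance across classes — the simplest structure consistent with reporting
per-class intercepts and slopes; richer covariance structures are out of
scope.  The patient-level marginal likelihood has compound-symmetry
covariance and is evaluated in closed form.

EM alternates responsibilities with exact weighted-GLS updates for the class
lines and a generalized M-step for the two variances (Nelder–Mead on the
log scale, accepted only when it improves the expected complete-data
log-likelihood, preserving EM monotonicity, which is asserted at every
iteration).  Restarts are deterministically seeded; a restart collapsing to
a class proportion below 1/(10 n) is discarded.  Classes are canonicalized
by ascending intercept.  BIC uses the number of patients as the sample size
(the subject-level-mixture convention); class counts are selected by lowest
BIC with ties to the smaller K.  With one class the model reduces to a
random-intercept linear model, which is cross-checked against an
independent mixed-model fit.  Mixture results are exploratory and feed
nothing downstream.

## Synthetic cohort generator

Defaults encode the study conditions the analyses assume: 41 + 41 patients;
lognormal follow-up (median 42 valid days, sigma 0.93, matching an IQR of
roughly 20–71); group daily MVPA means 46.9 vs 8.2 min (between-patient SDs
18 and 4, day-to-day SD 10); steps 8966 vs 5744; resting HR ≈ 70.7/70.6;
sleep timing near 24:00/7.8 h; three-wave PRO measures with baseline group
means and SDs near the documented cohort values and a configurable
group-by-time effect — the social-roles T-score interaction defaults to
−4.21 per 3 months, implemented as inactive-group improvement (+4.21/wave)
with a flat active group, matching the observed change-score pattern.
Between-patient and residual SDs for T-score measures split the ~10-point
baseline SD so that change scores also have ~10-point SDs.  Dropout is MCAR
at 0/30/30% per wave by default; MNAR modes (missingness logistic in the
value itself, offset calibrated to hit the target marginal rate) exist to
power the MCAR-test alternative simulations.

Minute streams carry a circadian sinusoid plus AR(1) noise around the
patient's resting HR, a sleep window with lowered HR and zero steps, and
activity minutes that raise intensity, METs, steps and HR jointly
(intensity >= 2 always implies METs > 3 and positive steps).  Step rates are
solved per day so the daily step total matches the patient's target given
their MVPA and light minutes.  HR values are integers, as devices report.
Artifacts are injected on disjoint windows and registered in a ledger:
missing-HR runs (placed on active minutes — fillable — or rest minutes —
nonwear), flat-line runs with lengths straddling the 11-minute rule (run
boundaries are adjusted so each injected run is maximal), and out-of-range
spikes (30 / 215 bpm).  T-score measures are not truncated (T-scores are not
hard-bounded); raw instruments are clipped to their documented ranges and
rounded.

What the generator does *not* emulate: wear-time compliance patterns
correlated with symptoms, device-specific drift, heteroscedastic or skewed
PRO noise, MAR mechanisms tied to observed covariates, and within-day
autocorrelation of activity bouts beyond the bout structure itself.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated conditions, not robustness to every real-data pathology.

## Problem sizes and numerical choices

Simulation studies in the test suite use the study's own scale where the
check depends on it (82 patients, 30% follow-up dropout, 200 replicates for
interaction recovery; 500 for test size; 50 two-class mixture replicates;
MCAR calibration at n = 200 over 200 null and 100 alternative replicates);
the oracle-equivalence check uses fifty 10,000-minute streams.  The
end-to-end drivers default to a quarter-scale cohort purely as a
convenience default for a worked example.  EM tolerance is 1e-6 relative
log-likelihood; mixed-model fits fall back from the default optimizer to
Powell before reporting failure; degenerate inputs (constant outcomes,
single-level factors, complete data in the MCAR test) raise or are flagged
explicitly rather than silently producing numbers.

## Known limitations

Satterthwaite/Kenward–Roger df are approximated by within/between df;
PROMIS raw-to-T conversion requires a user-supplied table; the Hawkins test
assumes multivariate normality; the mixture model fixes variances across
classes; timezone and daylight-saving reconciliation is out of scope
(timestamps are local civil time); and whole missing days are never
imputed.
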