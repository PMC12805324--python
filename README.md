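# wearcohort

Analysis pipeline for remote-monitoring cohorts that pair consumer wearable
(Fitbit-style) minute data with patient-reported outcomes (PROs), built for
longitudinal studies of long COVID and ME/CFS where activity phenotype and
symptom trajectories are analysed together.

The pipeline covers, end to end:

1. **Wear-time validation** of minute-level heart-rate streams: minutes with
   observed HR count as wear; missing-HR minutes with activity evidence
   (steps > 0, METs > 1.0 or a raised intensity code) are gap-filled with the
   mean of the nearest observed neighbours; implausible values (HR < 45 or
   > 205 bpm) and flat-line runs (>= 11 identical consecutive minutes) are
   excluded; a valid wear day has >= 1200 valid minutes (20 h) and a valid
   wear patient >= 7 valid days.
2. **Daily behavioural features**: MVPA minutes (intensity codes 2–3, i.e.
   > 3 METs), light minutes, sedentary fraction of wear time, steps, resting
   and maximum HR, sleep timing and efficiency; group tables use two-stage
   (patient-first) averaging.
3. **MVPA phenotyping** against the WHO guideline of 150 MVPA min/week
   (21.4 min/day): patients whose average daily MVPA over valid days reaches
   the threshold are MVPA-active, otherwise MVPA-inactive.
4. **PRO scoring**: PHQ-2 (0–6, flag at >= 3), GAD-7 (0–21), PROMIS raw
   domain sums and T-scores, CDC-style symptom severity composites
   (frequency x intensity, 0–16), three-level severity categories, and
   pairwise within-subject change scores.
5. **Cross-sectional statistics**: chi-squared / Student t / Wilcoxon chosen
   by data type and per-group Shapiro–Wilk normality; two-way ANOVA with
   Type II sums of squares; and a Hawkins-style k-sample test of the
   missing-completely-at-random hypothesis over missingness-pattern groups.
6. **Longitudinal mixed-effects models**: REML random-intercept models of
   PRO scores on time (3-month units), MVPA group, their interaction and the
   baseline score; ML-AIC model selection; Shapiro–Wilk and White-LM
   residual diagnostics; a sensitivity grid over thresholds, near-cutoff
   swaps, time codings and inclusion rules.
7. **Growth mixture modelling** of day-level series (daily MVPA, resting HR,
   steps): EM over latent-class linear trajectories with a patient random
   intercept, BIC class selection, posterior classification and entropy.
8. **Synthetic cohort generation** with a ground-truth ledger — minute
   streams with circadian HR, consistent activity bouts and injected sensor
   artifacts; sleep sessions; three-wave PRO tables with configurable
   group-by-time effects and MCAR dropout — so every stage can be scored
   against known truth.

The central longitudinal model, for patient *i* at wave *t* (0, 1, 2 in
3-month steps), is

    y_it = b0 + b1*t + b2*active_i + b3*(t x active_i) + b4*y_i0 + u_i + e_it,
    u_i ~ N(0, tau^2),  e_it ~ N(0, sigma^2)

where `b3` is the change per 3 months associated with being MVPA-active and
|b3| >= 3 T-score points is annotated as exceeding the conventional
meaningful-change threshold for PROMIS scales.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (scaled to a quarter of the full size by default for speed):

```bash
python analysis/01_simulate_cohort.py --seed 7
python analysis/02_validate_wear.py
python analysis/03_features_and_phenotypes.py
python analysis/04_cross_sectional.py
python analysis/05_longitudinal_lme.py
python analysis/06_trajectory_gmm.py
```

Representative output (seed 7):

```
valid wear patients: 20 / 20
exclusions (% of observed minutes): hr_below_min=0.007%, hr_above_max=0.006%, flatline_run=0.141%
flat-line cross-check: injected 1035 minutes (runs >= 11), pipeline flagged 1048

labels: {'inactive': 11, 'active': 9}
agreement with generating phenotype: 95.0%
group daily MVPA: active 51.6 (9.7) vs inactive 8.6 (3.5) min

published PHQ-2>=3 counts (8/41 vs 15/41): chi2=2.961, p=0.0853

social_roles_t: interaction -8.02 per 3 months (95% CI -13.55 to -2.49, p=0.0063)
recovery over 20 regenerated cohorts: mean estimate -4.77 (truth -4.21), CI coverage 0.90

mvpa_minutes: BIC chooses K=2 (intercepts [8.7, 52.2], sizes [11, 9], entropy 1.00)
resting_hr:  BIC chooses K=1 (intercepts [61.9], sizes [20])
```

Reading this: every simulated patient met the 7-valid-day rule; the
injected artifact counts are recovered almost exactly by the validation
stage (the excess 13 flat-line minutes are chance runs in the simulated HR
noise); phenotyping agrees with the generating phenotype for 19 of 20
patients (one patient's realized activity fell on the other side of the
21.4 min/day cutoff); the mixed model on this single quarter-scale cohort
estimates the interaction at -8.0 T points per 3 months — within its wide
CI of the generating value of -4.21, which the 20-cohort recovery line
centres much more closely; and the growth mixture finds two activity
classes in daily MVPA but a single class in resting HR, with class means
matching the generator.

The same stages are available as a console tool
(`wearcohort simulate|validate|features|phenotype|score|mcar|lme|gmm|run`),
e.g. `wearcohort run --out runs/demo --seed 7`, which writes per-stage
outputs plus a manifest recording every threshold, seed and output hash.

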