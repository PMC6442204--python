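# Methods

## The score and its units

All pressures are mmHg internally (1 mmHg = 1.36 cmH₂O; ventilator
displays in cmH₂O must pass through the explicit converter at the I/O
boundary). Creatinine is µmol/L internally, with a ×88.4 mg/dL converter
at the boundary. The effective renal perfusion pressure at a time point is

    RPP(t) = MAP(t) − (IAP(t) + CVP(t) + Pmean(t)),

evaluated on the admission-anchored grid 0/6/12/24/48 h. Missing inputs
propagate: a score value exists only where every required pressure does.
The single documented exception is the Pmean policy for patients who are
not mechanically ventilated — there is no airway pressure to transmit, so
under the default `pmean_policy="zero"` they contribute Pmean = 0 and the
combined score extends to the whole cohort; `pmean_policy="exclude"`
restricts the combined score to the ventilated subset with recorded Pmean,
which is how the source data were tabulated. A *ventilated* patient with a
missing Pmean stays missing under both policies: availability is taken
from the data, never derived from the flag.

## The decision rule

A patient is stratum A if the admission RPP is strictly below the
threshold (default 40.7 mmHg, the previously published admission median;
a value exactly at the threshold is *not* "below" — the injury claim is
stated for patients strictly below it). Above-threshold patients are
stratum C if the selected delta is strictly positive, else stratum B: a
delta of exactly zero is non-increase, and only an increase is
protective. Two delta definitions are first-class because the first 12
hours can be read two ways: `d0_12` = RPP(12) − RPP(0) (the default,
matching "increased in the first 12 h") and `d6_12` = RPP(12) − RPP(6)
(the interval whose group difference is statistically significant and
which feeds the ROC). The pipeline reports both side by side rather than
guessing. Patients with a missing admission value, or above-threshold
patients missing the selected delta, are reported as unclassifiable and
counted — never imputed.

## AKIN staging

Stage is the maximum of the creatinine and urine criteria (the AKIN
convention when they disagree), within the 0–48 h window anchored at ICU
admission, against the mandatory preoperative creatinine baseline.
Thresholds are pinned in one constants table in `staging.py`: creatinine
stage 1 = rise ≥ 26.5 µmol/L or ratio ≥ 1.5, stage 2 = ratio > 2.0,
stage 3 = ratio > 3.0 or level ≥ 354 µmol/L with an acute rise ≥ 44;
urine stage 1/2 = < 0.5 mL/kg/h for ≥ 6/≥ 12 consecutive hours, stage 3 =
< 0.3 for ≥ 24 h or anuria (< 0.05) for ≥ 12 h. Consecutiveness requires
contiguous recorded hours — a missing hour resets the run, which is the
conservative reading (oliguria is never fabricated across gaps). An
optional RRT flag forces stage 3 but is unused by the generator. A patient
with neither series raises an error; an outcome is never silently assumed
normal.

## The synthetic generator

The generator emulates the study conditions the analysis assumes: 84
patients, 34 ventilated (p = 0.405), an AKI target fraction of 39/84,
group-specific pressure medians per time point anchored to the emulated
cohort's published group tables, dropout of the 24/48 h pressure panels
(hazards chosen to reproduce the published per-timepoint n pattern:
no-AKI 0.07/0.25, AKI 0.05/0.05), and demographic rates (sepsis,
ventilation, mortality, surgery mix) matching the published counts.

Within-patient pressure evolution is a stationary AR(1) deviation per
field around the group median path, one step per grid interval, with
persistence 0.6 and marginal SDs (MAP 12, IAP 4, CVP 3, Pmean 2 mmHg).
No published summary constrains the persistence or the SDs; the SDs are
in the range implied by the published IQRs and the persistence is a
modelling choice, labelled as such. Pressures are clamped to the
plausibility windows and rounded to 0.1 mmHg *before* the outcome
mechanism runs, so the mechanism's verdict is computed on exactly the
values any re-analysis of the written CSVs sees (otherwise boundary cases
could flip between generation and analysis).

AKI status is the mechanism's verdict on the realized pressures: certain
below the threshold, impossible above it with a rising 0–12 h RPP, and
probability 0.8 in the above-threshold non-increasing stratum (the only
stratum where the emulated study reports mixed outcomes). A latent
intended group, drawn with the 39/84 target, selects which group's
medians a patient follows; because the per-field median paths do not
compose into the group RPP trajectories (medians of sums are not sums of
medians), a group-level MAP adjustment at 12 h steers the central 0–12 h
RPP change to the configured targets (+3 mmHg no-AKI, −6 mmHg AKI, the
published interval medians). The 12 h MAP marginal median therefore sits
at the configured median plus this documented offset; every other
field/time median converges to its configured value, and the test suite
checks both facts separately.

Creatinine and urine series are engineered for exact round-trip
recovery: stage-s patients get a monotone creatinine rise to a peak whose
ratio lies strictly inside stage s's band (AKI baselines are capped at
120 µmol/L so a stage-1/2 peak can never cross the absolute 354 µmol/L
branch), and an oliguric run realizing the same stage with probability
0.5 (so both criteria, alone and together, are exercised); stage-0
patients stay within +8 % of baseline and above 0.5 mL/kg/h throughout.
Dropout removes pressure panels only — creatinine and urine charting
continue to 48 h, so the outcome is stageable for every patient. All
randomness flows from one numpy Generator in a fixed draw order.

What the generator does **not** emulate: cross-field correlation within a
patient (off by default; the congestion terms were reported independent
in the emulated setting), vasopressor/fluid interventions, center
heterogeneity, and — importantly — the admission-level selection pattern
of real cohorts. Because AR(1) deviations revert to the mean, patients
with high admission RPP tend to decline and hence (via the mechanism) to
develop AKI, which attenuates or even reverses the admission-time group
difference in generated cohorts even though the 12 h and delta effects
reproduce the expected pattern (Hedges' g near 1 for the 6–12 h change).
Passing tests therefore validate the pipeline's mechanics and the
trajectory logic, not the admission-time epidemiology of real patients.

## Statistics

* Quartiles: linear interpolation of order statistics (numpy's default,
  "type 7"). SPSS's HAVERAGE rule can differ in the last digit on small
  samples; published IQRs are not re-derivable without raw data either way.
* Mann–Whitney: exact two-sided p by exhaustive enumeration of all
  C(n₁+n₂, n₁) labelings whenever both groups have ≤ 8 observations
  (covering the smallest subsets, n = 6 and 7, where asymptotics are
  dubious; midranks make the enumeration valid under ties), otherwise the
  normal approximation with tie and continuity corrections. All values
  tied ⇒ p = 1 exactly.
* Chi-square: Pearson's closed form without continuity correction by
  default (the primary statistic of the software family typically used
  for such analyses); Yates by flag. Zero margins raise, naming the
  margin.
* ROC: AUC is the Mann–Whitney probability (ties ½), identical by
  construction to U/(n₁n₂); operating point maximizes Youden's J over
  "positive if value ≥ t" thresholds; likelihood ratios with zero
  denominators are reported undefined. The 95 % CI on the AUC uses the
  Hanley–McNeil standard error. The positive class is always reported
  alongside the AUC, so an orientation like "1 − AUC" in a source table
  is disambiguated rather than guessed; for RPP *changes* the positive
  class defaults to no-AKI (a rising score indicates freedom from
  injury), keeping AUC > 0.5.
* Hedges' g: pooled-SD Cohen's d shrunk by J = 1 − 3/(4·df − 1).
* Stepwise logistic regression: forward entry by the Rao score test
  (entry p ≤ 0.05), backward re-check by Wald (removal p > 0.10) — the
  conventional defaults, both configurable. Likelihood maximization is
  statsmodels' Newton/IRLS; the score statistic, the selection loop and
  separation detection (non-convergence or diverging coefficients; the
  offending candidate is dropped and flagged) are implemented here. Wald
  is computed as (B/SE)² from unrounded values; note that recomputing a
  Wald statistic from *rounded* B and SE printed in a report will differ
  in the second decimal, which explains small discrepancies when checking
  published tables.
* Two-sided p-values throughout, significance at p ≤ 0.05, no
  multiple-testing correction (matching the analysis style being
  reconstructed); the stats bundle records the number of tests performed.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 84-patient cohorts for
pipeline checks (the emulated cohort size), 1000 patients for the staging
round trip, 2000 for median convergence (±1.5 mmHg), 200 small random
datasets for the exact-test oracle, 100 replicates at n = 500 for
logistic recovery, and 200 draws at n = 6 vs 17 for the small-sample
power check — sizes chosen to make stochastic checks stable at the stated
tolerances. Exact-oracle comparisons use 1e−12 tolerances; the χ²
closed-form/summation identity 1e−9; enumeration uses a 1e−9 guard on
midrank float sums. Logistic fits converge at tol 1e−8, max 100
iterations.

## Known limitations

* The generator's admission-time group difference is distorted by
  mean-reversion selection (see above); real cohorts separate earlier.
* The published sensitivity/specificity (86 %/81 %) and AUC of the real
  28-patient ventilated subset are not reproducible without patient-level
  data and are not claimed; the package reports its own cohorts' values.
* The attribution of the AUC confidence-interval formula in the source
  literature is ambiguous; Hanley–McNeil is implemented and named.
* Whether missing timepoints in real data arose from death, discharge or
  non-measurement is unknowable from the schema; the loader treats all as
  generic missingness.
* Severity scores (SAPS II, SOFA) and labs beyond creatinine are carried
  as input fields only and never computed or simulated.
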