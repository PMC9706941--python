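# Methods

## The problem

In locoregionally advanced nasopharyngeal carcinoma (LANPC), the prognosis
*after* a treatment failure depends strongly on when the failure occurred:
relapses soon after radiotherapy tend to reflect treatment-resistant
disease and carry a much higher post-failure death hazard than late
relapses. `failtiming` estimates the boundary between "early" and "late"
failure from the data — separately for locoregional recurrence and distant
metastasis — and quantifies how concurrent-chemotherapy intensity
(cumulative cisplatin dose, CCD: 0 / 1–200 / >200 mg/m²) shifts the timing
and risk of failure.

## Endpoints

All clocks start at treatment initiation, in months. OS is time to death
from any cause; LRFFS / DFFS time to first locoregional / distant failure;
FFS time to the first of any failure or death; post-failure OS is OS minus
the failure-free interval, defined only for patients with the failure and
separately per failure type (a patient with both failures contributes a
post-failure clock from each). Deaths without the relevant failure censor
LRFFS/DFFS at death — the conventional Kaplan–Meier/Cox treatment, not a
competing-risk estimator, and a known source of mild optimism in the
failure-free curves. At tied times, events precede censorings in the
risk-set update; times are compared exactly as stored.

## Minimum-P cut-point selection

For candidate months c the failure cohort splits into early
(interval ≤ c — "within c months" includes the boundary) and late; the
two post-failure survival curves are compared by the log-rank test. The
selected cut-off minimises P over the candidate grid.

*Grid and admissibility.* Candidates are the integer months between the
10th and 90th percentile of the observed failure-free intervals; a
candidate is admissible only if both arms keep ≥10% of the failure cohort
and ≥5 post-failure deaths. These guards (both configurable) prevent the
boundary artifacts that otherwise dominate minimum-P selection.

*Multiplicity correction.* The minimum of ~40 highly dependent log-rank P
values is strongly anti-conservative (measured type-I inflation: >20%
rejection at nominal 5%). The correction simulates the null distribution of
the minimum P by resampling, default **permutation**: failure-free intervals
are permuted against the (post-failure time, death) pairs, which is exactly
exchangeable under the null of no interval–survival association. A paired
**bootstrap** variant (pairs and intervals resampled independently) is
provided as an alternative since resampling schemes differ across the
literature. The corrected P uses the add-one Monte-Carlo estimator
(1 + #{null ≤ observed}) / (R + 1), never exactly zero; R defaults to 1000
and a warning is recorded below R = 100. Early/late group membership is
treated as fixed at failure time; the guarantee-time bias inherent in
defining groups by an event during follow-up is not corrected, matching
standard practice for this analysis.

## Cox modelling

`CoxPHModel` maximises the partial likelihood by Newton iteration with
step-halving (the negative log-likelihood is guaranteed non-increasing) to
a gradient max-norm of 1e-8; Efron tie handling is the default, Breslow
optional. Wald CIs and P values come from the inverse Hessian.
Non-convergence (typically monotone likelihood under separation, e.g. a
rare histology level with no events in one arm) is flagged on the result,
never silent. `BackwardEliminatedCox` first screens candidates by
univariable Wald P < 0.10 — the inclusion rule is read as a screening
step, and univariable Cox (not log-rank) is used for it — then removes
the largest-P covariate from the multivariable model until all retained
P < 0.05. Both thresholds are configurable. No multiplicity correction is
applied across endpoints or tables. Early-failure endpoints
(e.g. early-DFFS) administratively censor everyone at the selected cut-off;
late-failure endpoints are landmark analyses restricted to patients still
failure-free at the cut-off.

## Adjusted failure curves from a random survival forest

The forest engine is scikit-survival's `RandomSurvivalForest`: bootstrap
trees with log-rank split selection and Nelson–Aalen cumulative-hazard
estimates in the terminal nodes. Defaults: 1000 trees, mtry =
⌈√(#encoded features)⌉, terminal-node control 15 (mapped onto the
engine's `min_samples_leaf`, i.e. sample-count rather than event-count
semantics). A single unsplittable tree grown without bootstrap reproduces
the cohort Nelson–Aalen estimator exactly — the oracle for the whole
prediction path. Individual curves are F(t|x) = 1 − exp(−Ĥ(t|x)) with the
ensemble-averaged Ĥ step-interpolated onto an integer-month grid.

Group curves are **adjusted by g-computation / partial dependence**: for
each CCD level g, every cohort member's group covariate is set to g while
their other covariates (sex, age, smoking, family history, T stage, N
stage by default) are kept, and individual F(t) values are averaged — the
standard forest-compatible standardisation over the empirical covariate
distribution. A random subsample of profiles (default 500) may be used as
a Monte-Carlo version of the same average. Monthly time-specific
probabilities are first differences f(m) = F(m) − F(m−1), smoothed by a
centred 3-month moving average (edges truncated; window configurable, 1 =
raw differences), clipped at zero and rescaled once so the running sum
equals F at the horizon exactly. With smoothing, the running sum matches F
exactly at the horizon (and everywhere for window 1), not month-by-month.
The composite "treatment failure" endpoint for these curves is the first
of locoregional or distant failure, with death censoring.

## The synthetic cohort generator

The generator emulates the study conditions of a 3123-patient LANPC
cohort; its defaults are the package's fixed study conditions, not tuning
knobs:

- **Covariates** drawn independently from the published marginal
  frequencies (74.4% male, 54.2% age ≤45, 97.2% WHO III, 86.7% T3-4,
  52.1% N2-3, 50.8% stage IVa, 57.2% EBV DNA ≥4000 copies/ml, CCD groups
  22.7 / 71.4 / 5.9%, ...). Real between-covariate associations (e.g. CCD
  allocation varying with age and IC cycles) are deliberately not
  reproduced: only marginals are published.
- **Latent times** for locoregional failure, distant failure and
  failure-free death follow piecewise-constant proportional hazards,
  elevated during the first 48 months (failure concentrates in the early
  follow-up years) and reduced fourfold after. Baseline levels
  (2.098e-3, 2.169e-3, 1.423e-4 events/month) were calibrated once against
  the analytic oracle so the observed first-event fractions equal the
  reported 13.0% locoregional recurrence, 16.4% distant metastasis and
  19.8% deaths; they are frozen constants. Only the first event among the
  three latent channels and censoring is recorded; the other failure
  channel is censored at the final time, so no secondary failures are
  simulated.
- **Change-point structure**: the post-failure death hazard (0.019/month
  baseline) is multiplied by exp(1.1) when the failure precedes the true
  cut-off — 14 months (locoregional) or 20 months (distant). This is the
  ground truth the cut-point scan must recover.
- **Treatment effects** follow the published multivariable directions:
  N2-3, stage IVa and high EBV load raise the distant-failure hazard;
  CCD 1–200 and >200 mg/m² multiply the *early-window* (t ≤ 20 months)
  distant-failure hazard by 0.763 and 0.351.
- **Censoring** is administrative, uniform on 48–96 months (median
  follow-up ≈ 67 months, matching the reported scale).

`expected_event_fractions` integrates the same model numerically
(covariate-mixture enumeration × piecewise-exponential competing risks,
with a closed form for the post-failure death-before-censoring
probability) and serves as the generator's independent oracle: Monte-Carlo
agreement is verified at 10⁶ draws in the test suite.
`simulate_failure_cohort` generates failure cohorts directly
(truncated-exponential intervals, constant post-failure hazard with the
change-point multiplier) for scan power and calibration studies where only
the failure cohort matters.

What the generator does *not* emulate — covariate dependence, secondary
failures, salvage-treatment effects on post-failure survival (the salvage
label is an independent categorical), non-proportional baseline effects,
loss to follow-up — bounds what passing tests show: they certify the
estimators under a correctly specified piecewise-exponential world, not
robustness to real-data violations.

## Numerical choices

- Log-rank variance uses the hypergeometric form with the (n−d)/(n−1) tie
  factor; zero-variance candidates are reported as inadmissible (NaN), and
  a scan whose candidates are all degenerate raises.
- Cox Newton steps solve the Hessian system directly, falling back to
  least-squares on singularity; up to 30 step-halvings per iteration.
- The forest's candidate thresholds sit at observed covariate values with
  deterministic seeded tie-breaking (delegated to the engine); constant
  covariate columns are dropped before fitting.
- Pipeline stage seeds are master_seed + fixed offsets (0, 101, 102, 103,
  104), so any stage can be re-run in isolation; reports serialise times
  to 6 decimal places and probabilities to 10 significant digits, and
  identical configurations give byte-identical JSON.

## Problem sizes in the test suite

Simulation-based checks are sized for a single CPU: change-point recovery
uses 100 replicates of 400-failure cohorts per endpoint (±2-month recovery
≥80%); null calibration of the corrected minimum P uses 400 replicates of
300-failure cohorts at 500 resamples (rejection within 3–7% at α = 0.05,
raw minimum P >10%); Cox recovery uses 100 replicates at n = 3000; the
forest effect-direction study uses 50 replicates at n = 1500 with 500
trees and a balanced three-arm CCD allocation — under the study's 5.9%
high-dose share that arm contributes only a handful of early events, and
the check would measure allocation noise rather than the estimator. The
early-window effect is assessed as the adjusted cumulative failure
probability through month 20, the quantity the ln(0.351) early-window
log-hazard ratio acts on. The end-to-end pipeline check runs n = 3000 with
500 trees and 500 resamples, twice, and requires byte-identical reports.

## Known limitations

- LRFFS/DFFS treat death as censoring; with ~20% mortality the failure-free
  curves are modestly optimistic versus a competing-risk analysis.
- The early/late contrast conditions on surviving to the failure
  (guarantee-time bias); the scan optimises post-failure survival
  separation, which is the intended estimand, but the early/late KM curves
  inherit the bias.
- The minimum-P approach yields cut-offs with substantial sampling
  variability at realistic failure-cohort sizes (±2 months around a true
  change-point at ~400–500 failures); corrected P values, not the raw
  minimum, should be quoted.
- Forest-adjusted group curves shrink true group differences (regularisation
  toward the cohort average) and show spurious gaps of up to a few
  percentage points at n ≤ 2500 under a null effect; differences smaller
  than that scale should not be over-interpreted.
- No proportional-hazards diagnostics, frailty terms, time-varying
  covariates or competing-risk (Fine–Gray) models are provided.
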