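# Methods

This note records the statistical model behind each stage of the pipeline,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions.

## Analysis model

The estimand is the incremental cost and QALY contrast between the
intervention and control arms of a 1:1 randomised trial over 3- and
12-month horizons.

**Costs.** Costs are cumulative: the 12-month total is the 0–3-month
recall window plus the 3–12-month window, with the per-person intervention
cost (screening + prognosis-matched treatment) incurred in the first
window. Because individual health-care costs are right-skewed and strictly
positive, between-arm cost contrasts are estimated as ratios of means from
a gamma GLM with log link. Zero totals (possible for control-arm
participants with no health-care use) are shifted by half the smallest
positive observed cost — zero cells only, with the count recorded on the
fit; a two-part hurdle model is out of scope. Adjusted per-arm means come
from marginal standardization (predict all participants under each arm and
average); with a log link the standardized-mean ratio equals
exp(arm coefficient) exactly, so ratio inference is carried out on the log
scale and exponentiated.

**QALYs.** Utility weights at 0/0.25/1.0 years (AQoL-8D instrument range
[-0.04, 1]) are integrated by the trapezoidal rule with exact time
denominators 0.25 and 0.75 years; no visit-date jitter and no mortality
(none is expected in a 12-month primary-care depression cohort). QALY
contrasts use a Gaussian/identity GLM that always adjusts for baseline
utility in covariate-adjusted fits.

**Covariates.** The protocol set is baseline PHQ-9, general practice
(fixed indicators — no multilevel model) and prognostic group; subgroup
fits drop the group covariate. An extended set mirroring non-response
predictors (age, gender, education, employment, health-care card,
long-term illness, living alone, past psychologist/psychiatrist visits,
antidepressant use) is available as the `nonresponse_extended` variant.
Per-horizon outcomes are fitted as separate cross-sectional GLMs on
cumulative totals — the simplest reading consistent with one observation
per participant per horizon; a repeated-measures formulation is not
implemented.

## Missing data

Follow-up loss hits the resource-use questionnaire (RUQ) and the utility
instrument wave-wise; baselines are always complete. Imputation is
multiple imputation by chained equations with predictive mean matching:

- Variables are visited in order of increasing missingness. Each visit
  fits a linear model of the target on the baseline predictor set (trial
  arm, clinic, age, gender, education, past psychologist/counsellor
  visits) plus the other imputation variables at their current values.
- Coefficients are perturbed by an approximate posterior draw (normal
  around the fit with estimated covariance; residual variance from a
  scaled chi-square draw). Missing rows are matched to the k = 5 observed
  rows with nearest predictions (type-1 matching: donors ranked under the
  maximum-likelihood fit, targets predicted under the perturbed draw) and
  one donor's observed value is copied uniformly at random. Imputed values
  are therefore always observed values — the support and skewness of cost
  variables survive imputation.
- Defaults: m = 100 imputations for point estimation (tests and the
  acceptance script scale this to 5–20), 10 chained-equation sweeps,
  k = 5 donors. One master seed spawns independent substreams per
  imputation and per bootstrap replicate, so changing m or B never
  correlates draws.
- Imputation happens on the measured quantities (utility weights, valued
  window costs) and QALYs/cost totals are derived per completed dataset;
  imputing QALYs directly is available behind the `impute_on: qalys`
  config flag.

Point estimates pool across completed datasets by Rubin's rules (total
variance = within + (1 + 1/m)·between; t reference with the standard MI
degrees of freedom). Ratio contrasts pool on the log scale.

Uncertainty for decision quantities uses *single imputation nested in
bootstrapping*: each bootstrap resample (stratified by trial arm by
default; `arm_x_group` and unstratified modes exist) receives one chained
imputation before the GLMs are refitted. A replicate whose fit fails (for
example a resample losing a covariate level) is redrawn from a fresh
substream; more than 5% redraws aborts the run.

## Decision layer

The ICER is ΔC/ΔE of adjusted-mean contrasts, classified as *dominant*
(cheaper, more effective) or *dominated* (costlier, less effective) when a
ratio is not meaningful. Percentile CIs order the bootstrap draws by angle
on the cost-effectiveness plane, sweeping counter-clockwise from the pure
cost-saving direction (ΔE = 0, ΔC < 0): dominant quadrant first, then the
north-east quadrant with ICER rising from 0 to ∞, then dominated, then
south-west. This stays well-defined when draws straddle ΔE = 0, where raw
ICER quantiles are meaningless; a raw-quantile mode is provided for
comparison. Bounds landing in dominance quadrants are reported as labels
("Dominant to Dominated"). When more than 2.5% of draws fall in the
south-west quadrant the upper bound is a south-west ratio (savings per
QALY forgone) — a documented property of the angular convention, printed
as a number.

CEACs use the strict net-monetary-benefit rule P(λ·ΔE − ΔC > 0) on a
default λ grid of 0 to 150,000 in steps of 1,000; ties count as not
cost-effective (a measure-zero event). The λ = 0 and λ → ∞ limits equal
the fractions of draws with ΔC < 0 and ΔE > 0 exactly, which the test
suite asserts.

## Synthetic trial generator

The generator emulates the trial the analysis assumes, with every
distributional target recorded in `GeneratorTruth` so `truth_summary`
returns closed-form expected contrasts.

- **Allocation**: stratum sizes by largest-remainder rounding of the group
  proportions; within-stratum arm imbalance resolved by deterministic
  alternating assignment. The `target_d` preset pins the exact published
  splits (679/678, 143/145, 111/112) directly, since alternation alone
  cannot produce every printed near-equal split.
- **Costs**: a per-participant gamma "spend" target (shape 0.35 per
  stratum for health care, 0.5 for productivity; coefficient of variation
  ≈ 1.7) is decomposed into Poisson category counts with means
  share·spend/unit-cost. Valuing the counts recovers the gamma mean
  exactly, quantities are integers, and skewness is positive in every
  stratum × arm cell. Productivity spend is split 60/40 in value between
  paid and unpaid days at wage rates 180 and 90 A$/day (unpaid = half the
  paid rate; whether and how the study valued unpaid work is not
  determinable, so both the split and the rate are config).
- **Arm effects**: uniform per-stratum multiplicative ratios on cumulative
  health-sector totals (preset: 0.99 at 3 m, 0.91 at 12 m), so conditional
  and marginal ratios coincide and the covariate-adjusted GLM estimand
  equals the configured truth. Utility shifts are additive and uniform
  across strata (+0.016 at 3 m, +0.008 at 12 m), giving QALY differences
  of exactly 0.002 and 0.011.
- **Utilities**: normals truncated to [-0.04, 1] by *location-solving* —
  the location parameter is found by root-finding so the truncated mean
  equals the target cell mean exactly (clipping or naive truncation would
  bias the means and hence the QALY contrast). Control-arm cell means are
  calibrated to the published mean QALYs per stratum; SD 0.2.
- **Dependence**: a Gaussian copula links the seven latent variables
  (three utilities, four window spends): utilities exchangeable at 0.6,
  cost windows at 0.5, cost–utility cross-correlation 0 by default
  (independence given stratum) and exposed in config because CEAC values
  are sensitive to it.
- **Clinic effects**: random intercepts across 14 practices — additive on
  the utility location (SD 0.02) and multiplicative mean-one lognormal on
  cost (SD 0.05 on the log) — so the "general practice" covariate has
  something to adjust for.
- **Missingness**: wave-wise MAR through a logistic model on standardised
  age, gender, education and past psychologist visits, with the intercept
  solved numerically (root-finding to <1e-4 in expected rate) to hit the
  target rates 46/60% (RUQ) and 49/66% (utilities) at 3/12 months. The
  3 m/12 m within-instrument dependence is a latent correlation parameter
  defaulting to 0, because the published union/per-wave figures do not
  identify the joint structure. MCAR and all-zero-target modes exist; no
  MNAR mechanism is provided.

What the generator does *not* emulate: item-level instrument scoring,
visit-date variation, PHQ-9 symptom trajectories as a clinical endpoint,
informative (MNAR) missingness, and any cost–utility dependence beyond
the stratum-shared structure unless the copula parameter is raised. A
pipeline that passes recovery tests here is validated for its estimators
under MAR — not for robustness to MNAR loss or measurement error in real
trial data.

## Numerical choices

- Gamma GLMs fit by IRLS (tolerance 1e-10, 300 iterations). Small
  subgroups with an extreme observation can put IRLS into a period-2 limit
  cycle; the fit then falls back to direct BFGS minimisation of the
  deviance (the gamma/log coefficient MLE — the scale profiles out), with
  covariance scale·(XᵀX)⁻¹ and Pearson-X² scale, identical to the IRLS
  estimator. Convergence is accepted only if the deviance gradient norm is
  small; otherwise the fit raises.
- PMM donor search is O(n log n) per variable via a sorted-prediction
  window of 2k candidates; ties at window edges are resolved by partial
  sort. Perfect predictor collinearity raises an error naming the
  offending columns.
- The trial-size arithmetic uses exact count-based proportions
  (1357/1868, 288/1868, 223/1868); the rounded percentages 72.6/15.4/11.9
  do not sum to 1 and are only display values.
- All randomness flows from `numpy` `SeedSequence` spawning; regeneration
  with the same seed is byte-identical, and run manifests record SHA-256
  hashes of every CSV/JSON artifact (figures are regenerated from hashed
  inputs; their bytes additionally depend on the matplotlib build, whose
  version the manifest records).
- Problem sizes in the test suite and acceptance script are scaled
  (m = 5–20, B in the low hundreds, 50–100 recovery replications) — the
  package's own choice of validation scale; defaults for real analyses
  remain m = 100, B = 1,000.

## Known limitations

- The gamma zero-shift policy biases ratios slightly when zeros are
  frequent; the generator produces them rarely (only via all-zero Poisson
  counts at low spend).
- Rubin t-based CIs at small m are conservative; recovery tests observe
  coverage near the upper half of the 95% ± 4 pp band.
- The angular CI convention is one defensible choice among several; raw
  quantiles are provided but are only meaningful when no draw crosses
  ΔE = 0.
- Generator utility noise (SD 0.2) is somewhat larger than the published
  standard errors imply for the real cohort, so synthetic CEACs are
  flatter (acceptability probabilities closer to 50%) than the published
  curves even at matched effect sizes.
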