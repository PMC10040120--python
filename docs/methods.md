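# Methods

`mimecorrect` implements and evaluates two corrections for self-report
measurement error in health-interview surveys that carry a randomly drawn
examination (validation) subsample: regression calibration and multiple
imputation for measurement error (MIME). This note records the statistical
model behind each component, the defaults and why they were chosen, and what
the synthetic evaluation does and does not establish.

## The measurement-error problem

Interview surveys ask respondents for their height, weight and diagnosed
conditions; examination surveys measure them. Self-reports are biased:
height is over-reported and weight under-reported (more so by women, the
elderly and — for height — the less educated), so BMI-based indicators are
underestimated; self-reported hypertension and hypercholesterolemia behave
like diagnostic tests with high specificity but low sensitivity, because the
conditions are largely asymptomatic. When the examination subsample is drawn
completely at random from the interview sample, respondents with and without
measurements are exchangeable, so the missing measured values are missing
(completely) at random and both corrections below are identified.

## Synthetic survey generator

The generator (`mimecorrect.synthetic`) defines the evaluation conditions;
its defaults were fixed once to emulate published agreement statistics for a
national interview/examination survey pair and are not tuned per experiment.

* **Population.** Age uniform on 18–90; sex ~ Bernoulli(0.51); education in
  4 ordered levels (8/22/35/35%); 11 provinces; household size 1 + Poisson(1.3)
  capped at 8. Height is a sex-specific normal (176.5/163.5 cm, SD 6.8) with
  0.05 cm/yr shrinkage after 45. True BMI is right-skewed,
  18 + Gamma(1.9, 4.4) plus a small age trend, giving ~50% overweight
  (BMI ≥ 25) and ~22–23% obesity; weight is BMI × height², which fixes the
  joint distribution. Hypertension and hypercholesterolemia flags are
  Bernoulli with age-increasing probability centred on 33% and 47%;
  continuous blood pressure, medication use and total cholesterol are then
  drawn *consistently with the flags* (truncated normals inside the normal
  range, elevated/treated mixtures for cases), so every indicator is
  exercised through its threshold definition (sbp ≥ 140 OR dbp > 90 OR
  medication; cholesterol > 190 mg/dl, medication deliberately excluded
  because statins are widely used preventively; BMI ≥ 25 / ≥ 30).
* **Self-report error.** Continuous:
  `sr = true + bias(subgroup) + (b − 1)(true − mean_sex) + ε`,
  a global attenuation slope `b = 0.85` ("flat slope": low values
  over-reported, high values under-reported) centred within sex, plus
  intercept-level bias by sex/age/education and Gaussian noise (2.6 cm /
  3.5 kg). The defaults give a mean height bias ≈ +1.1 cm, weight ≈ −1.5 kg,
  BMI ≈ −0.9 kg/m², and an implied obesity self-report operating point of
  roughly sens 0.72 / spec 0.99. Binary conditions are misclassified with
  sensitivity/specificity 0.45/0.99 (hypertension) and 0.22/0.83
  (hypercholesterolemia). The slope is centred within sex so that the
  subgroup bias pattern keeps the sign of its intercepts for both sexes.
* **Design.** Stratum from province, clusters nested within strata, and a
  deterministic positive weight rule that over-weights the elderly, men and
  the less educated (emulating non-response corrections). The validation
  subsample is selected completely at random (default fraction 1184/9439).
* What the generator does **not** emulate: real weighting algorithms
  (raking/calibration), informative non-response, geographic structure
  beyond labels, within-cluster correlation of outcomes, or reporting error
  that depends on the measured value beyond the linear flat slope. Passing
  tests therefore demonstrate correctness of the estimators under a clean
  MCAR validation design, not robustness to violations of it.

## Step 1 — validity metrics

Agreement on the validation subsample (`mimecorrect.validity`): Bland–Altman
mean difference with limits of agreement mean ± 1.96·SD (survey-weighted
means/SDs; CI for the mean via the paired-t machinery, for the limits via the
large-sample SE `sd·√(3/n)`), paired t-test, and the two-way
absolute-agreement single-measure ICC (ICC(A,1)) from the paired ANOVA mean
squares — absolute agreement rather than consistency, because a systematic
reporting shift is exactly what should be penalised. Binary conditions get
weighted 2×2 confusion summaries (sensitivity/specificity/PPV/NPV), Cohen's
kappa on the weighted table, and McNemar's χ² `(b−c)²/(b+c)` on *unweighted*
discordant counts (a weighted exact reference distribution is not well
defined). Undefined ratios from empty margins propagate as NaN, never 0.
All metrics can be stratified by sex, age band (18–24/25–44/45–64/65+) or
education; small strata are flagged, not dropped.

## Step 2a — regression calibration

For each outcome a model predicting the measured value from the self-report,
age, sex and education (linear for height/weight, logistic for the binary
conditions) is fitted on the validation subsample. Candidate
self-report × covariate interactions are screened forward in the fixed order
age, sex, education (education as a joint 3-df Wald block) and kept at
p < 0.05. Accuracy is the held-out R²/AUC from a 70/30 split stratified on
the binary outcome (avoiding single-class test sets at small n); by default
the selected specification is then refitted on the whole validation sample
for substitution (`refit_full=False` disables). Logistic fits fall back to a
ridge-penalized Newton fit under separation, which keeps saturated
predictions saturated while bounding coefficients.

Calibrated continuous values are predicted means; corrected BMI is recomputed
from predicted height and weight; calibrated binary "values" are predicted
probabilities and the calibrated prevalence is their weighted mean (no
arbitrary 0.5 classification rule). The SE of a calibrated prevalence adds a
delta-method term `g'Vg` for calibration-coefficient uncertainty to the
design-based variance of the weighted mean of predictions; without that term
the SE of a weakly predictive model's nearly constant predictions would be
absurdly small. The deeper limitation of calibration — substituting single
predictions rather than draws, so completed values understate real
variability — is not repaired; it is the reason the imputation route exists.

## Step 2b — multiple imputation for measurement error

`mimecorrect.mice` is a from-scratch chained-equations engine. Measured
height, weight and the two binary measured indicators of non-validation
respondents are treated as missing data; covariate item nonresponse can be
imputed in the same sweep. Predictors default to the self-report of the
condition plus age, sex, education, household size and province (wave year
when multi-wave), i.e. the variables behind the survey weighting; the weight
itself is not a predictor. Visit order defaults to least-missing first.
Chains are initialised by draws from each variable's observed values;
observed cells are never overwritten; BMI and the overweight/obesity flags
are derived passively from each completed copy and never imputed directly.

* **PMM (continuous, parametric).** Bayesian linear regression:
  σ² drawn from the scaled inverse-χ² at the ridge-stabilised OLS fit, then
  a coefficient draw; observed rows are ranked by posterior-mean predictions
  and missing rows by drawn-coefficient predictions (type-1 matching); each
  missing row takes the observed y of one of its 5 nearest donors (donor
  count configurable; 5 is the conventional default).
* **Logistic (binary, parametric).** Coefficient draw from the normal
  approximation at the MLE (ridge-penalized refit under separation);
  missing rows imputed as Bernoulli draws. A single observed class falls
  back to shrunken-prevalence Beta draws.
* **Random forest (either type).** Each call first draws an *outer
  bootstrap* of the observed rows — the nonparametric analogue of the
  parametric coefficient draw — then grows `n_trees` trees, each on its own
  bootstrap of that resample (sklearn decision trees; mtry = p/3, terminal
  node size 5 for regression and 1 for classification). A missing row is
  dropped down one randomly chosen tree and imputed by a uniform draw among
  the in-bag observed responses in its terminal node. Donor draws keep
  continuous imputations inside the observed-value set (no impossible BMIs)
  and preserve residual variability.

  Two deliberate departures from common defaults, both found necessary by
  bias/variance diagnostics on the generator: (1) *the outer bootstrap.*
  Without it, each row's independent random-tree choice averages the model's
  sampling uncertainty away across the ~85% of rows being imputed, and the
  between-imputation variance misses the dominant uncertainty source — the
  finite validation sample; pooled SEs were ~2.5× too small for the weakly
  predicted conditions. (2) *mtry = p/3 for classification too* (instead of
  √p): with ~10 dummy-coded province columns, √p starves a weak age gradient
  of split opportunities and measurably attenuates covariate trends in the
  weighted estimates.
* **Convergence.** The mean and SD of the imputed values are logged per
  chain × iteration × variable. `convergence_summary` compares between- to
  within-chain spread of the mean trace over a trailing window as a
  potential-scale-reduction-style ratio and flags variables above 1.2 (the
  conventional PSRF cut-off). With the default predictor set the chains have
  no cross-variable feedback and mix immediately; the diagnostic exists for
  configurations with covariate missingness or chained predictors, and for
  detecting genuinely divergent runs.

Defaults `m = 10`, 100 iterations, 100 trees follow standard practice for
public-use completed datasets (with relative efficiency (1 + γ/m)⁻¹ > 99%
when γ ≲ 0.1); development and test profiles scale these down (typically
m = 5, 3–10 iterations, 20 trees, n ≈ 1,000–2,400 with a 300-person
validation subsample) to keep replicate simulations inside ordinary CI
budgets — the statistical properties tested are size-stable.

## Step 3 — pooling and design-based inference

Prevalence is the weighted ratio mean Σwᵢyᵢ/Σwᵢ with Taylor-linearized
variance under with-replacement sampling of clusters within strata
(`n_h/(n_h−1) Σ_c (z_hc − z̄_h)²` on the linearized scores). Strata with a
single cluster are collapsed into one pseudo-stratum by default (an `error`
policy exists). Estimates across completed datasets combine by Rubin's
rules: T = W̄ + (1 + 1/m)B, fraction of missing information
γ = (1 + 1/m)B/T, relative efficiency (1 + γ/m)⁻¹, and Barnard–Rubin
degrees of freedom with complete-data df = clusters − strata. CIs are
symmetric on the proportion scale (matching conventional survey reporting);
no logit transform is applied.

The SE-ratio report divides the validation-only design SE by the corrected
full-sample SE: ratios above 1 mean the corrected interview sample is more
precise than the small examination sample alone. In the synthetic
evaluation this holds essentially always for the well-predicted indicators
(overweight, obesity, strong binary operating points) and for the
random-forest imputation throughout, while regression calibration's
advantage collapses as model accuracy falls — the qualitative pattern that
motivates preferring imputation when the self-report is weakly informative.

## Numerical and degenerate-input conventions

Ridge ε = 1e-5 stabilises all normal-equation solves; logistic linear
predictors are clipped at ±35 (±30 in the ridge fallback) before the
sigmoid; posterior covariance matrices are symmetrised before Cholesky.
Constant outcomes short-circuit to constant imputations; single-class
logistic outcomes use shrunken-prevalence draws; a degenerate (single-node)
tree reduces to a bootstrap draw from the observed values. Zero-variance
paired differences return a degeneracy flag instead of a p-value; empty
confusion margins return NaN. All randomness flows from
`numpy.random.SeedSequence` spawns of a single master seed, so every result
is bit-for-bit reproducible from (parameters, seed).

## Known limitations

* Coverage statements are calibrated against the weighted superpopulation
  prevalence. With m = 5 and a nearly uninformative self-report the
  between-imputation variance is estimated from 4 degrees of freedom, so a
  fixed ±2·SE band has nominal coverage ≈ 0.88 rather than 0.95 even for a
  perfectly proper imputer; the t-based Rubin interval (which the package
  reports) does not have this defect. Evaluations that demand ≥ 90%
  within-2-SE rates at m = 5 for high-FMI indicators sit at or beyond this
  nominal ceiling.
* The random-forest imputer propagates validation-sampling uncertainty via
  the outer bootstrap; this is an approximation, not an exact posterior, and
  can be mildly conservative for strongly predicted variables.
* Regression-calibration SEs cover coefficient uncertainty but not the
  substitution bias inherent to single-prediction replacement.
* McNemar's test is the asymptotic χ² form; no exact/conditional variant,
  and no multi-rater ICC.
* No raking/calibration weight construction and no replication-weight
  (jackknife/BRR) variance estimation.
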