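# mimecorrect

Correction of self-report measurement error in health-interview surveys that
include a randomly drawn examination (validation) subsample.

Population surveillance of overweight, obesity, hypertension and
hypercholesterolemia usually relies on what respondents *say* about their
height, weight and diagnoses. Self-reports are systematically wrong: height
is over-reported and weight under-reported (so BMI-based prevalence is
underestimated), and asymptomatic conditions are reported with high
specificity but low sensitivity. When a random subsample of the same
respondents also receives objective measurements, the error can be corrected.
This package implements, end to end:

1. **Validity analysis** — Bland–Altman limits of agreement
   (mean difference ± 1.96·SD), paired t-tests, ICC(A,1), weighted confusion
   matrices with sensitivity/specificity/PPV/NPV, Cohen's kappa and McNemar's
   test, stratified by sex, age band and education.
2. **Regression calibration** — replace each self-report by the prediction of
   a model fitted on the validation subsample (self-report + age, sex,
   education; Wald-screened interactions; 70/30 held-out R²/AUC), recompute
   BMI from predicted height and weight.
3. **Multiple imputation for measurement error (MIME)** — treat the measured
   values of non-examined respondents as missing data and multiply impute
   them by chained equations, either parametrically (predictive mean
   matching + logistic posterior draws) or with a donor-based random forest
   (bootstrap trees; each missing row imputed by a draw from a random tree's
   terminal node).
4. **Design-based pooling** — survey-weighted prevalence with
   Taylor-linearized variance (strata/clusters/weights), combined across the
   m completed datasets by Rubin's rules
   (T = W̄ + (1 + 1/m)B, Barnard–Rubin df, fraction of missing information,
   relative efficiency (1 + γ/m)⁻¹), plus the SE-ratio comparison:
   examination-only SE / corrected full-sample SE.

A synthetic survey generator with known truth (flat-slope continuous error,
sensitivity/specificity misclassification, stratified clustered weighted
design, MCAR validation subsample) makes every stage testable without access
to restricted microdata.

## Worked example

```python
import mimecorrect as mc
from mimecorrect import mice, pooling, workflow

# interview survey of 2,000 with a 300-person examination subsample
df = mc.generate_survey(mc.TruthParams(n_respondents=2000),
                        design=mc.DesignParams(validation_fraction=0.15),
                        seed=1)

# naive self-reported vs truth
print(workflow.self_reported_estimates(df).round(3))

# random-forest multiple imputation, pooled by Rubin's rules
spec = mice.default_spec("rf", data=df, m=5, n_iterations=5, n_trees=20, seed=2)
completed = mice.run_chained(df, spec)
cols = {"obesity": "obesity_completed", "hypertension": "meas_hypertension"}
print(pooling.analyze_completed(completed, cols).round(4)
      [["indicator", "qbar", "se", "fmi", "relative_efficiency"]])
```

Output (seed 1):

```
              indicator  estimate     se
0            overweight     0.473  0.011
1               obesity     0.167  0.008
2          hypertension     0.156  0.008
3  hypercholesterolemia     0.201  0.010

      indicator    qbar      se     fmi  relative_efficiency
0       obesity  0.2378  0.0160  0.6218               0.8894
1  hypertension  0.3444  0.0198  0.7164               0.8747
```

The self-reported prevalences (obesity 16.7%, hypertension 15.6%) are far
below the generated truth (23.1% and 33.8%); the pooled imputation estimates
(23.8% and 34.4%) recover it, and the reported SE carries the within- and
between-imputation variance (fraction of missing information 0.62 and 0.72 —
these indicators are mostly imputed information, since 85% of respondents
have no measurement and the self-reports are weak predictors).

The same pipeline is available as numbered analysis scripts
(`analysis/01_simulate.py` … `analysis/05_pool_compare.py`, writing their
tables under `results/`) and as a CLI:

```bash
mimecorrect simulate --n 2000 --seed 1 --out survey.csv
mimecorrect validity --data survey.csv --variable bmi --out validity.csv
mimecorrect all --config configs/reduced.yaml
```

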