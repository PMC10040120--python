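"""Generate the working survey: a health-interview sample with an
examination (validation) subsample.

Writes results/survey.csv plus a provenance sidecar.  The generated file
mirrors the structure of a national interview survey: every respondent has
error-prone self-reports; measured height/weight/blood-pressure/cholesterol
exist only for the randomly drawn examination subsample (~12.5%).
"""

from pathlib import Path

import mimecorrect as mc
from mimecorrect import synthetic, workflow

SEED = 2018
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    truth = mc.TruthParams()          # 9,439 respondents
    error = mc.ErrorParams()          # flat-slope + misclassification defaults
    design = mc.DesignParams()        # 1,184-person examination subsample
    df = mc.generate_survey(truth, error, design, seed=SEED)
    violations = workflow.validate_schema(df)
    assert not violations, violations
    synthetic.write_dataset(
        df, OUT / "survey.csv", seed=SEED,
        params={"truth": truth, "error": error, "design": design},
    )
    n_val = int(df["in_validation"].sum())
    print(f"wrote {len(df)} respondents ({n_val} with examination data) "
          f"to {OUT / 'survey.csv'}")
    print("true prevalences:",
          {c: round(float(df[f'true_{c}'].mean()), 3)
           for c in ("overweight", "obesity", "hypertension",
                     "hypercholesterolemia")})


if __name__ == "__main__":
    main()
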