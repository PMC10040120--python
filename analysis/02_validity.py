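"""Step 1 of the analysis: how far do self-reports deviate from measurements?

Uses the examination subsample to quantify agreement: Bland-Altman mean
difference and limits of agreement with ICC for height/weight/BMI, and
confusion-matrix summaries (sensitivity, specificity, PPV, NPV, kappa,
McNemar) for the binary conditions, stratified by sex, age band and
education.  Writes results/validity_*.csv.
"""

from pathlib import Path

import pandas as pd

from mimecorrect import synthetic, validity

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    df = synthetic.read_dataset(OUT / "survey.csv")
    frames = []
    for var in ("height", "weight", "bmi",
                "overweight", "obesity", "hypertension", "hypercholesterolemia"):
        for strata in ("sex", "age_band", "education"):
            reps = validity.stratified_validity(df, var, strata)
            t = validity.reports_to_frame(reps)
            t.insert(0, "variable", var)
            t.insert(1, "strata", strata)
            frames.append(t)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(OUT / "validity_stratified.csv", index=False)

    whole = table[table["stratum"] == "all"].drop_duplicates(["variable"])
    print("whole-population agreement (self-reported vs measured):")
    cont = whole[whole["variable"].isin(["height", "weight", "bmi"])]
    print(cont[["variable", "mean_diff", "loa_lower", "loa_upper", "icc"]]
          .round(2).to_string(index=False))
    binr = whole[~whole["variable"].isin(["height", "weight", "bmi"])]
    print(binr[["variable", "sensitivity", "specificity", "kappa",
                "prevalence_sr", "prevalence_meas"]].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
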