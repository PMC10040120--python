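"""End-to-end pipeline: simulate/load -> validity -> calibrate -> impute -> pool.

A single :class:`RunConfig` drives the whole analysis reproducibly; every
output directory receives a ``manifest.json`` recording the configuration,
the master seed and the package version, from which the run can be repeated
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, calibration, indicators, mice, pooling, synthetic, validity

logger = logging.getLogger(__name__)

INDICATOR_NAMES = ["overweight", "obesity", "hypertension", "hypercholesterolemia"]


@dataclass
class RunConfig:
    """One pipeline run.

    Exactly one of ``input_csv`` (pre-existing survey file) or ``generator``
    (parameter dict / YAML section for the synthetic generator) must be set.
    ``methods`` selects which corrections to run.
    """

    input_csv: str | None = None
    generator: dict = field(default_factory=dict)
    methods: tuple = ("calibration", "mice-parametric", "mice-rf")
    m: int = 10
    n_iterations: int = 100
    n_trees: int = 100
    pmm_donors: int = 5
    seed: int = 0
    output_dir: str = "results"
    weighted: bool = True

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def validate(self):
        if self.input_csv and self.generator:
            raise ValueError("configure exactly one input source (csv OR generator)")
        bad = set(self.methods) - {"calibration", "mice-parametric", "mice-rf"}
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")


SCHEMA_NUMERIC_RANGES = {
    "sr_height": (100.0, 250.0),
    "sr_weight": (25.0, 300.0),
    "meas_height": (100.0, 250.0),
    "meas_weight": (25.0, 300.0),
}
REQUIRED_COLUMNS = [
    "stratum", "cluster", "weight", "age", "sex", "education", "province",
    "household_size", "sr_height", "sr_weight", "sr_hypertension",
    "sr_hypercholesterolemia", "in_validation",
]


def validate_schema(data: pd.DataFrame, column_mapping: dict | None = None) -> list:
    """Check column presence, unit ranges, weight positivity and the
    validation-subsample missingness pattern.  Returns a list of violation
    strings (empty when the dataset is well formed); nothing is coerced."""
    df = data.rename(columns=column_mapping or {})
    violations = []
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            violations.append(f"missing column: {col}")
    if violations:
        return violations
    if (df["weight"] <= 0).any():
        violations.append("non-positive weights")
    for col, (lo, hi) in SCHEMA_NUMERIC_RANGES.items():
        if col in df.columns:
            v = df[col].dropna()
            if ((v < lo) | (v > hi)).any():
                violations.append(f"{col} outside ({lo}, {hi})")
    in_val = df["in_validation"] == 1
    for col in synthetic.MEASURED_COLUMNS:
        if col not in df.columns:
            violations.append(f"missing column: {col}")
            continue
        if df.loc[~in_val, col].notna().any():
            violations.append(f"{col} present outside the validation subsample")
        if df.loc[in_val, col].isna().any():
            violations.append(f"{col} missing inside the validation subsample")
    return violations


def self_reported_estimates(data: pd.DataFrame, design=None) -> pd.DataFrame:
    """Naive survey-weighted prevalences from the self-reports alone."""
    design = design or pooling.DesignColumns()
    df = data.copy()
    sr_bmi = indicators.bmi(df["sr_weight"], df["sr_height"])
    df["sr_overweight"] = indicators.overweight_flag(sr_bmi)
    df["sr_obesity"] = indicators.obesity_flag(sr_bmi)
    rows = []
    for name in INDICATOR_NAMES:
        est, var = pooling.weighted_prevalence(df, f"sr_{name}", design)
        rows.append({"indicator": name, "estimate": est, "se": float(np.sqrt(var))})
    return pd.DataFrame(rows)


def validation_only_estimates(data: pd.DataFrame, design=None) -> pd.DataFrame:
    """Design-based prevalences using the examination measurements alone."""
    design = design or pooling.DesignColumns()
    val = data[data["in_validation"] == 1].copy()
    ind = indicators.derive_indicators(
        val["meas_height"], val["meas_weight"], sbp=val["meas_sbp"],
        dbp=val["meas_dbp"], htn_medication=val["meas_htn_medication"],
        tchol=val["meas_total_cholesterol"],
    )
    for name in INDICATOR_NAMES:
        val[f"meas_{name}_flag"] = ind[name].to_numpy()
    rows = []
    for name in INDICATOR_NAMES:
        est, var = pooling.weighted_prevalence(val, f"meas_{name}_flag", design)
        rows.append({"indicator": name, "estimate": est, "se": float(np.sqrt(var))})
    return pd.DataFrame(rows)


def run_calibration(data: pd.DataFrame, seed: int, design=None):
    """Fit the four calibration models, substitute predictions, and return
    (models, per-indicator estimate/SE table)."""
    design = design or pooling.DesignColumns()
    val = data[data["in_validation"] == 1]
    models = {}
    for i, outcome in enumerate(["height", "weight", "hypertension", "hypercholesterolemia"]):
        models[outcome] = calibration.fit_calibration(val, outcome, seed=seed + i)
    calibrated = calibration.calibrate_dataset(data, models)
    rows = []
    for name in INDICATOR_NAMES:
        if name in ("overweight", "obesity"):
            est, var = pooling.weighted_prevalence(calibrated, f"{name}_cal", design)
        else:
            est, var = pooling.calibrated_prevalence(data, models[name], design)
        rows.append({"indicator": name, "estimate": est, "se": float(np.sqrt(var))})
    return models, calibrated, pd.DataFrame(rows)


def run_mice(data: pd.DataFrame, approach: str, config: RunConfig, design=None):
    """One chained-equations run plus pooled prevalence table."""
    design = design or pooling.DesignColumns()
    spec = mice.default_spec(
        approach="rf" if approach == "mice-rf" else "parametric",
        data=data,
        m=config.m,
        n_iterations=config.n_iterations,
        n_trees=config.n_trees,
        pmm_donors=config.pmm_donors,
        seed=config.seed + (1000 if approach == "mice-rf" else 2000),
    )
    completed = mice.run_chained(data, spec)
    cols = {
        "overweight": "overweight_completed",
        "obesity": "obesity_completed",
        "hypertension": "meas_hypertension",
        "hypercholesterolemia": "meas_hypercholesterolemia",
    }
    table = pooling.analyze_completed(completed, cols, design)
    return completed, table


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; write tables under ``output_dir`` and
    return the result bundle as a dict of DataFrames."""
    config.validate()
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_csv:
        data = synthetic.read_dataset(config.input_csv)
    else:
        params = {
            "truth": synthetic.TruthParams(**config.generator.get("truth", {})),
            "error": synthetic.ErrorParams(**config.generator.get("error", {})),
            "design": synthetic.DesignParams(**config.generator.get("design", {})),
        }
        data = synthetic.generate_survey(
            params["truth"], params["error"], params["design"], seed=config.seed
        )
    violations = validate_schema(data)
    if violations:
        raise ValueError("schema violations: " + "; ".join(violations))

    design = pooling.DesignColumns()
    results = {}
    logger.info("validity stage")
    reports = []
    for var in ("height", "weight", "bmi", "hypertension", "hypercholesterolemia"):
        reports.extend(validity.stratified_validity(data, var, "sex", weighted=config.weighted))
    results["validity"] = validity.reports_to_frame(reports)

    results["self_reported"] = self_reported_estimates(data, design)
    results["validation_only"] = validation_only_estimates(data, design)

    pooled_tables = {}
    if "calibration" in config.methods:
        logger.info("calibration stage (%.1fs)", time.time() - t0)
        models, _, table = run_calibration(data, config.seed, design)
        results["calibration_models"] = pd.DataFrame(
            [m.to_dict() | {"coefficients": None} for m in models.values()]
        )
        (out / "calibration_models.json").write_text(
            json.dumps({k: v.to_dict() for k, v in models.items()}, indent=2)
        )
        pooled_tables["calibration"] = table
    for approach in ("mice-parametric", "mice-rf"):
        if approach in config.methods:
            logger.info("%s stage (%.1fs)", approach, time.time() - t0)
            completed, table = run_mice(data, approach, config, design)
            pooled_tables[approach] = table
            results[f"{approach}_trace"] = completed.trace
            window = max(2, min(10, config.n_iterations))
            results[f"{approach}_convergence"] = mice.convergence_summary(
                completed.trace, window=window
            )

    comparison = results["self_reported"].rename(
        columns={"estimate": "self_reported", "se": "self_reported_se"}
    )
    comparison = comparison.merge(
        results["validation_only"].rename(
            columns={"estimate": "validation_only", "se": "validation_only_se"}
        ),
        on="indicator",
    )
    ratio_rows = []
    for method, table in pooled_tables.items():
        key = method.replace("-", "_")
        sub = table.rename(
            columns={"estimate": key, "qbar": key, "se": f"{key}_se"}
        )[["indicator", key, f"{key}_se"]]
        comparison = comparison.merge(sub, on="indicator")
        for _, r in comparison.iterrows():
            ratio_rows.append(
                pooling.se_ratio(
                    f"{r['indicator']}:{method}", r["validation_only_se"], r[f"{key}_se"]
                ).to_dict()
            )
    results["comparison"] = comparison
    results["se_ratios"] = pd.DataFrame(ratio_rows)

    for name, table in results.items():
        if isinstance(table, pd.DataFrame):
            table.to_csv(out / f"{name.replace('-', '_')}.csv", index=False)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "seed": config.seed,
        "version": __version__,
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return results
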