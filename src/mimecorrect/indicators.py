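"""Risk-factor indicator definitions.

Cut-offs follow the standard surveillance definitions: overweight/obesity from
WHO BMI categories, hypertension from a single-visit 140/90 rule plus
medication use, and hypercholesterolemia from total serum cholesterol alone
(lipid-lowering medication deliberately excluded, since statins are widely
used preventively).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BMI_OVERWEIGHT = 25.0  # kg/m^2, inclusive
BMI_OBESITY = 30.0  # kg/m^2, inclusive
SBP_CUTOFF = 140.0  # mmHg, inclusive
DBP_CUTOFF = 90.0  # mmHg, strict >
TCHOL_CUTOFF = 190.0  # mg/dl, strict >


def bmi(weight_kg, height_cm):
    """Body mass index in kg/m^2 from weight in kg and height in cm."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    if np.any(weight_kg[~np.isnan(weight_kg)] <= 0) or np.any(
        height_cm[~np.isnan(height_cm)] <= 0
    ):
        raise ValueError("height and weight must be strictly positive")
    return weight_kg / (height_cm / 100.0) ** 2


def overweight_flag(bmi_vals):
    """1 if BMI >= 25 kg/m^2 (obesity included), else 0; NaN propagates."""
    return _threshold_flag(bmi_vals, BMI_OVERWEIGHT, inclusive=True)


def obesity_flag(bmi_vals):
    """1 if BMI >= 30 kg/m^2, else 0; NaN propagates."""
    return _threshold_flag(bmi_vals, BMI_OBESITY, inclusive=True)


def hypertension_flag(sbp, dbp, on_medication):
    """1 if sbp >= 140 mmHg OR dbp > 90 mmHg OR antihypertensive medication."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    med = np.asarray(on_medication, dtype=float)
    flag = (sbp >= SBP_CUTOFF) | (dbp > DBP_CUTOFF) | (med > 0)
    out = flag.astype(float)
    out[np.isnan(sbp) | np.isnan(dbp) | np.isnan(med)] = np.nan
    return out


def hypercholesterolemia_flag(tchol):
    """1 if total serum cholesterol > 190 mg/dl (strict), else 0."""
    return _threshold_flag(tchol, TCHOL_CUTOFF, inclusive=False)


def _threshold_flag(values, cutoff, inclusive):
    values = np.asarray(values, dtype=float)
    flag = values >= cutoff if inclusive else values > cutoff
    out = flag.astype(float)
    out[np.isnan(values)] = np.nan
    return out


def derive_indicators(
    height_cm,
    weight_kg,
    sbp=None,
    dbp=None,
    htn_medication=None,
    tchol=None,
) -> pd.DataFrame:
    """Derive all indicators from continuous measurements.

    Returns a DataFrame with columns ``bmi``, ``overweight``, ``obesity`` and,
    when blood pressure / cholesterol inputs are given, ``hypertension`` and
    ``hypercholesterolemia``. Flags are floats (0/1) so missingness can
    propagate as NaN.
    """
    out = pd.DataFrame(
        {
            "bmi": bmi(weight_kg, height_cm),
        }
    )
    out["overweight"] = overweight_flag(out["bmi"])
    out["obesity"] = obesity_flag(out["bmi"])
    if sbp is not None:
        if dbp is None or htn_medication is None:
            raise ValueError("hypertension requires sbp, dbp and medication flag")
        out["hypertension"] = hypertension_flag(sbp, dbp, htn_medication)
    if tchol is not None:
        out["hypercholesterolemia"] = hypercholesterolemia_flag(tchol)
    return out
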