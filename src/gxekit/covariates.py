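"""Covariate schema shared by the simulator and the association models.

Categorical domains and reference levels follow the descriptive table of the
emulated cohort study: age 20-39, female, income < NT$20k, normal BMI,
college/university education, no exercise, never smoker, occasional drinker
and comorbidity-free are the reference levels.  The simulator draws covariates
from the non-case (control) marginal distributions of that table so that the
synthetic cohort is demographically realistic without any external data.
"""

from __future__ import annotations

# var -> ordered levels, reference level FIRST (design matrices expand the rest)
CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "age_group": ["20-39", "40-59", "60-79"],
    "sex": ["female", "male"],
    "income": ["<20k", "20-30k", "30-40k", ">40k"],
    "bmi_class": ["normal", "underweight", "overweight", "obesity1", "obesity2", "obesity3"],
    "education": ["college", "lt_high_school", "high_school", "postgraduate"],
    "exercise": ["no", "yes"],
    "smoking": ["never", "former", "current"],
    "drinking": ["occasional", "quit", "regular"],
    "hypertension": ["no", "yes"],
    "hyperlipidemia": ["no", "yes"],
    "depression": ["no", "yes"],
}

# Control-group marginal probabilities (column % of non-cases), same level
# order as CATEGORICAL_LEVELS; normalised at draw time.
CONTROL_MARGINALS: dict[str, list[float]] = {
    "age_group": [22.91, 56.33, 20.74],
    "sex": [64.44, 35.55],
    "income": [54.07, 18.69, 26.58, 0.64],
    "bmi_class": [60.69, 3.29, 29.14, 5.79, 0.88, 0.17],
    "education": [48.51, 11.15, 28.69, 11.62],
    "exercise": [60.49, 39.50],
    "smoking": [80.77, 9.95, 9.26],
    "drinking": [2.46, 91.63, 5.90],
    "hypertension": [89.54, 10.45],
    "hyperlipidemia": [93.84, 6.15],
    "depression": [96.45, 3.54],
}

# Adjustment sets for the multivariable models.
MODEL1_COVARIATES = [
    "age_group", "sex", "income", "bmi_class",
    "education", "exercise", "smoking", "drinking",
]
MODEL2_COVARIATES = MODEL1_COVARIATES + ["hypertension", "depression", "hyperlipidemia"]

ADJUSTMENT_SETS: dict[str, list[str]] = {
    "crude": [],
    "model1": MODEL1_COVARIATES,
    "model2": MODEL2_COVARIATES,
}


def dummy_name(var: str, level: str) -> str:
    """Design-matrix column name for a non-reference level indicator."""
    return f"{var}[{level}]"


def dummy_columns(var: str) -> list[str]:
    """Indicator column names for every non-reference level of ``var``."""
    return [dummy_name(var, lev) for lev in CATEGORICAL_LEVELS[var][1:]]
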