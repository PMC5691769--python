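"""Cohort data model: schema, CSV I/O, and derived-variable definitions.

The canonical in-memory representation of a cohort is a :class:`pandas.DataFrame`
with one row per participant and the columns documented in :data:`SCHEMA`.
Hemoglobin is carried in g/L throughout (anemia thresholds 130/120 g/L for
men/women); readers may declare other units and are converted on ingest.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import CohortParseError, ValidationError

# --------------------------------------------------------------------------
# Schema
# --------------------------------------------------------------------------

SEX_LEVELS = ("female", "male")
REGION_LEVELS = ("north", "south")
EDUCATION_LEVELS = ("low", "medium", "high")
OCCUPATION_LEVELS = ("manual", "non_manual")
SMOKING_LEVELS = ("none", "light", "heavy")
INCOME_LEVELS = ("low", "medium", "high")

#: Numeric encoding of the three household-income levels (Yuan/person).
INCOME_YUAN = {"low": 1000.0, "medium": 3500.0, "high": 5000.0}

#: Food-group intake columns, g/day.
FOOD_COLUMNS = (
    "rice",
    "wheat",
    "other_cereals",
    "total_meat",
    "organ_meat",
    "other_meat",
    "total_vegetable",
    "legumes",
    "fruit",
    "soy_sauce",
)

#: Derived macro-/micronutrient columns (total_calories kcal/day, iron mg/day,
#: fibre and macronutrients g/day, micronutrients mg/day unless noted).
NUTRIENT_COLUMNS = (
    "total_calories",
    "protein",
    "fat",
    "carbohydrate",
    "fibre",
    "iron",
    "copper",
    "magnesium",
    "manganese",
    "phosphorus",
    "potassium",
    "selenium",
    "zinc",
    "vitamin_a",
    "vitamin_b1",
    "vitamin_b2",
    "vitamin_c",
)

INTAKE_COLUMNS = FOOD_COLUMNS + NUTRIENT_COLUMNS

CLINICAL_COLUMNS = (
    "height",
    "weight",
    "waist",
    "sbp",
    "dbp",
    "glucose",
    "triglycerides",
    "hdl",
    "total_cholesterol",
    "hemoglobin",
    "ferritin",
)

CATEGORICAL_VOCABS: Mapping[str, tuple[str, ...]] = {
    "sex": SEX_LEVELS,
    "region": REGION_LEVELS,
    "education": EDUCATION_LEVELS,
    "occupation": OCCUPATION_LEVELS,
    "smoking": SMOKING_LEVELS,
    "income_level": INCOME_LEVELS,
}

FLAG_COLUMNS = ("urban", "on_antihypertensives", "anemia_baseline")

#: Columns every cohort file must carry.
REQUIRED_COLUMNS = (
    ("id", "sex", "age", "region", "education", "occupation", "smoking",
     "income_level")
    + FLAG_COLUMNS
    + CLINICAL_COLUMNS
    + INTAKE_COLUMNS
)

#: Columns a cohort file may carry in addition (follow-up state and
#: re-derivable flags written by ``derive``).
OPTIONAL_COLUMNS = (
    "followed_up",
    "anemia_followup",
    "anemia",
    "low_iron",
    "obese",
    "hypertension",
    "diabetes",
    "metabolic_syndrome",
    "income_numeric",
)

#: Sex-specific anemia thresholds, g/L, strict "below".
ANEMIA_THRESHOLD = {"male": 130.0, "female": 120.0}

#: Low-iron thresholds, mg/day, strict "below". Women aged 18-49 use the
#: higher cutoff; everyone else the lower one.
LOW_IRON_FEMALE_18_49 = 20.0
LOW_IRON_DEFAULT = 12.0


# --------------------------------------------------------------------------
# Classification rules
# --------------------------------------------------------------------------

def classify_anemia(hemoglobin, sex):
    """Flag anemia from hemoglobin (g/L) with sex-specific strict thresholds.

    Parameters
    ----------
    hemoglobin : float or array-like
        Hemoglobin concentration in g/L; must be positive.
    sex : str or array-like
        ``"female"`` or ``"male"`` (element-wise for arrays).

    Returns
    -------
    bool or ndarray of bool
        True iff hemoglobin < 130 g/L (men) or < 120 g/L (women).
    """
    hb = np.asarray(hemoglobin, dtype=float)
    if np.any(hb <= 0):
        raise ValidationError("hemoglobin must be positive (g/L)")
    sex_arr = np.asarray(sex)
    threshold = np.where(sex_arr == "male", ANEMIA_THRESHOLD["male"],
                         ANEMIA_THRESHOLD["female"])
    result = hb < threshold
    if np.isscalar(hemoglobin) or result.ndim == 0:
        return bool(result)
    return result


def classify_low_iron(iron, sex, age):
    """Flag low daily iron intake (mg/day) against guideline thresholds.

    Low iff intake < 20 mg/day for women aged 18-49 (inclusive), or
    < 12 mg/day for everyone else. Both cutoffs are strict.
    """
    fe = np.asarray(iron, dtype=float)
    if np.any(fe < 0):
        raise ValidationError("iron intake must be non-negative (mg/day)")
    sex_arr = np.asarray(sex)
    age_arr = np.asarray(age, dtype=float)
    premenopausal = (sex_arr == "female") & (age_arr >= 18) & (age_arr <= 49)
    threshold = np.where(premenopausal, LOW_IRON_FEMALE_18_49, LOW_IRON_DEFAULT)
    result = fe < threshold
    if np.isscalar(iron) or result.ndim == 0:
        return bool(result)
    return result


def encode_income(level):
    """Map an income level (``low``/``medium``/``high``) to Yuan/person."""
    if isinstance(level, str):
        if level not in INCOME_YUAN:
            raise ValidationError(f"unknown income level: {level!r}")
        return INCOME_YUAN[level]
    levels = pd.Series(level)
    unknown = set(levels.dropna()) - set(INCOME_YUAN)
    if unknown:
        raise ValidationError(f"unknown income level(s): {sorted(unknown)!r}")
    return levels.map(INCOME_YUAN).to_numpy()


def _flag_where_complete(flag: np.ndarray, complete: np.ndarray) -> np.ndarray:
    """Return float flag array with NaN wherever inputs were incomplete."""
    out = flag.astype(float)
    out[~complete] = np.nan
    return out


def derive_clinical_flags(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach all derived flags to a cohort table.

    Adds ``anemia``, ``low_iron``, ``obese``, ``hypertension``, ``diabetes``,
    ``metabolic_syndrome`` (floats in {0, 1, NaN}; NaN where the inputs were
    missing) and ``income_numeric``. Pure function of the row: calling it
    twice is idempotent.

    Definitions
    -----------
    - obese: BMI = weight / (height/100)^2 strictly above 28 kg/m^2
    - hypertension: antihypertensive medication, SBP > 140, or DBP > 90 mmHg
    - diabetes: fasting glucose > 7.0 mmol/L
    - metabolic syndrome: central obesity (waist >= 90 cm men / >= 80 cm
      women) and at least two of: TG >= 150 mg/dL, glucose >= 5.6 mmol/L,
      SBP >= 130 or DBP >= 85 mmHg, HDL < 40 (men) / < 50 (women) mg/dL.
    """
    df = cohort.copy()
    n = len(df)
    sex = df["sex"].to_numpy()
    male = sex == "male"

    hb = df["hemoglobin"].to_numpy(dtype=float)
    ok = np.isfinite(hb)
    anemia = np.zeros(n, dtype=bool)
    if np.any(hb[ok] <= 0):
        raise ValidationError("hemoglobin must be positive (g/L)")
    anemia[ok] = hb[ok] < np.where(male[ok], 130.0, 120.0)
    df["anemia"] = _flag_where_complete(anemia, ok)

    fe = df["iron"].to_numpy(dtype=float)
    age = df["age"].to_numpy(dtype=float)
    ok = np.isfinite(fe) & np.isfinite(age)
    low_iron = np.zeros(n, dtype=bool)
    low_iron[ok] = classify_low_iron(fe[ok], sex[ok], age[ok])
    df["low_iron"] = _flag_where_complete(low_iron, ok)

    height = df["height"].to_numpy(dtype=float)
    weight = df["weight"].to_numpy(dtype=float)
    ok = np.isfinite(height) & np.isfinite(weight) & (height > 0)
    bmi = np.full(n, np.nan)
    bmi[ok] = weight[ok] / (height[ok] / 100.0) ** 2
    df["obese"] = _flag_where_complete(bmi > 28.0, ok)

    sbp = df["sbp"].to_numpy(dtype=float)
    dbp = df["dbp"].to_numpy(dtype=float)
    meds = df["on_antihypertensives"].to_numpy(dtype=float)
    ok = np.isfinite(sbp) & np.isfinite(dbp) & np.isfinite(meds)
    hyper = (meds > 0) | (sbp > 140.0) | (dbp > 90.0)
    df["hypertension"] = _flag_where_complete(hyper, ok)

    glucose = df["glucose"].to_numpy(dtype=float)
    ok = np.isfinite(glucose)
    df["diabetes"] = _flag_where_complete(glucose > 7.0, ok)

    waist = df["waist"].to_numpy(dtype=float)
    tg = df["triglycerides"].to_numpy(dtype=float)
    hdl = df["hdl"].to_numpy(dtype=float)
    ok = (np.isfinite(waist) & np.isfinite(tg) & np.isfinite(glucose)
          & np.isfinite(sbp) & np.isfinite(dbp) & np.isfinite(hdl))
    central = waist >= np.where(male, 90.0, 80.0)
    criteria = (
        (tg >= 150.0).astype(int)
        + (glucose >= 5.6).astype(int)
        + ((sbp >= 130.0) | (dbp >= 85.0)).astype(int)
        + (hdl < np.where(male, 40.0, 50.0)).astype(int)
    )
    df["metabolic_syndrome"] = _flag_where_complete(central & (criteria >= 2), ok)

    df["income_numeric"] = encode_income(df["income_level"])
    return df


# --------------------------------------------------------------------------
# Height calibration
# --------------------------------------------------------------------------

def calibrate_by_height(intakes: pd.DataFrame, height, sex,
                        method: str = "residual") -> pd.DataFrame:
    """Remove height covariation from intake columns, separately per sex.

    ``method="residual"`` (default): within each sex, each column is replaced
    by its residual from a simple linear regression on height, plus the
    sex-specific column mean (scale preserved, height correlation removed).
    ``method="ratio"``: columns are divided by height and rescaled by the
    sex-specific mean height.

    A sex stratum with constant height is passed through unchanged with a
    warning.
    """
    if method not in ("residual", "ratio"):
        raise ValidationError(f"unknown calibration method: {method!r}")
    height = np.asarray(height, dtype=float)
    sex = np.asarray(sex)
    out = intakes.astype(float).copy()
    for level in np.unique(sex):
        mask = sex == level
        h = height[mask]
        if mask.sum() < 3:
            raise ValidationError(
                f"need at least 3 participants per sex, got {mask.sum()} for {level!r}")
        if np.ptp(h) == 0:
            warnings.warn(
                f"constant height within sex {level!r}; calibration is the identity")
            continue
        block = out.loc[mask].to_numpy()
        if method == "residual":
            hc = h - h.mean()
            slopes = hc @ block / (hc @ hc)
            block = block - np.outer(hc, slopes)
        else:
            block = block / h[:, None] * h.mean()
        out.loc[mask] = block
    return out


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

_NUMERIC_COLUMNS = ("age",) + CLINICAL_COLUMNS + INTAKE_COLUMNS


def read_cohort(path, hemoglobin_unit: str = "g/L") -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`CohortParseError` naming the offending column for missing
    or unknown columns, out-of-vocabulary categories, and non-numeric values
    in numeric columns. ``hemoglobin_unit`` may be ``"g/L"`` (canonical) or
    ``"g/dL"`` (multiplied by 10 on ingest).
    """
    if hemoglobin_unit not in ("g/L", "g/dL"):
        raise CohortParseError(f"unknown hemoglobin unit: {hemoglobin_unit!r}")
    try:
        df = pd.read_csv(path, dtype={"id": str})
    except pd.errors.EmptyDataError:
        raise CohortParseError(f"empty cohort file: {path}")
    if df.empty:
        raise CohortParseError(f"cohort file has no rows: {path}")

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError(f"missing required column(s): {missing}")
    known = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise CohortParseError(f"unknown column(s): {unknown}")

    for col, vocab in CATEGORICAL_VOCABS.items():
        bad = ~df[col].isin(vocab) & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortParseError(
                f"bad category in column {col!r} at row {row}: {df[col].iloc[row]!r}")
    for col in _NUMERIC_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            raise CohortParseError(f"non-numeric value in numeric column {col!r}")
    if hemoglobin_unit == "g/dL":
        df["hemoglobin"] = df["hemoglobin"] * 10.0
    if df["id"].duplicated().any():
        raise CohortParseError("duplicate participant ids")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV (full float precision, round-trip safe)."""
    cohort.to_csv(path, index=False)


def split_by_sex(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition a cohort into its sex strata."""
    return {level: cohort[cohort["sex"] == level] for level in SEX_LEVELS}


def require_columns(cohort: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort is missing column(s): {missing}")
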