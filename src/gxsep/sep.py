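"""Socioeconomic position (SEP) indicators and dichotomised risk factors.

Two SEP indicators are derived from raw phenotype fields:

* education — total years of formal education, categorised into four bands
  (≤10, 11–13, 14–17, ≥18 years) and dichotomised at 14 years
  (low < 14 vs high ≥ 14);
* income — monthly household net income divided by a household
  equivalisation weight, then ranked within sex into quartiles and
  dichotomised at the sex-specific median (high = strictly above).

Risk factors (ever-smoking, obesity at BMI ≥ 30, diabetes by glucose /
history / medication criteria, and low food-frequency intake of fish,
vegetables and fruit) are coded as binaries per the printed criteria.
Missing inputs propagate as missing so that complete-case exclusion can be
done per model downstream.

Quantile cut points use lower order statistics (type-1), never
interpolation, so label assignment is rank-stable across platforms; values
tied at a cut point go to the lower group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EDUCATION_BANDS",
    "FFQ_LEVELS",
    "code_education",
    "equivalize_income",
    "sex_specific_quantiles",
    "code_risk_factors",
    "flc_ratio_flag",
]

EDUCATION_BANDS = ("<=10", "11-13", "14-17", ">=18")
EDUCATION_HIGH_CUT = 14.0  # years; high education is >= 14

#: Food-frequency questionnaire levels, most to least frequent.
FFQ_LEVELS = (
    "daily",
    "4-6 times/week",
    "1-3 times/week",
    "1-3 times/month",
    "hardly ever/never",
)
_FFQ_RANK = {lab: i for i, lab in enumerate(FFQ_LEVELS)}

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


def code_education(years: pd.Series | float) -> pd.DataFrame:
    """Categorise education years into the four bands and the 14-year binary.

    Returns a DataFrame with columns ``education_cat4`` (ordered categorical
    ``<=10 < 11-13 < 14-17 < >=18``) and ``education_high`` (1.0 if
    years ≥ 14, 0.0 if below, NaN where years is missing).
    """
    y = pd.Series(years, dtype=float) if not isinstance(years, pd.Series) else years.astype(float)
    if (y.dropna() < 0).any():
        raise ValueError("education years must be non-negative")
    cat = pd.cut(
        y,
        bins=[-np.inf, 10, 13, 17, np.inf],
        labels=list(EDUCATION_BANDS),
        ordered=True,
    )
    high = pd.Series(np.where(y.isna(), np.nan, (y >= EDUCATION_HIGH_CUT).astype(float)), index=y.index)
    return pd.DataFrame({"education_cat4": cat, "education_high": high})


def equivalize_income(
    household_income: pd.Series | float, household_weight: pd.Series | float
) -> pd.Series | float:
    """Household net income per equivalent member: income / weight (€/month)."""
    w = np.asarray(household_weight, dtype=float)
    if np.any(w[~np.isnan(w)] <= 0):
        raise ValueError("household weight must be > 0")
    out = np.asarray(household_income, dtype=float) / w
    if isinstance(household_income, pd.Series):
        return pd.Series(out, index=household_income.index, name="equivalized_income")
    return float(out)


def _type1_quantile(sorted_vals: np.ndarray, frac: float) -> float:
    """Lower order statistic at probability ``frac`` (quantile type 1)."""
    n = len(sorted_vals)
    return float(sorted_vals[max(int(np.ceil(frac * n)) - 1, 0)])


def sex_specific_quantiles(
    income: pd.Series, sex: pd.Series, tie_policy: str = "lower"
) -> pd.DataFrame:
    """Quartile and median-split labels computed within each sex separately.

    ``income_quartile`` is Q1..Q4 by within-sex lower-order-statistic cut
    points; ``income_high`` is 1.0 iff income is strictly above that sex's
    median. Ties at a cut point go to the lower group (``tie_policy`` is
    fixed to ``"lower"``; a degenerate stratum where all incomes are equal
    raises).

    Raises
    ------
    ValueError
        If any sex stratum is empty, has fewer than 4 non-missing incomes,
        or has all incomes identical.
    """
    if tie_policy != "lower":
        raise ValueError("only tie_policy='lower' is implemented")
    income = income.astype(float)
    quart = pd.Series(pd.NA, index=income.index, dtype="object")
    high = pd.Series(np.nan, index=income.index, dtype=float)

    for sx in pd.unique(sex.dropna()):
        mask = (sex == sx) & income.notna()
        vals = income[mask]
        if len(vals) < 4:
            raise ValueError(f"sex stratum {sx!r} has fewer than 4 incomes")
        if vals.nunique() == 1:
            raise ValueError(f"sex stratum {sx!r} has all incomes equal; quartiles undefined")
        ordered = np.sort(vals.to_numpy())
        cuts = [_type1_quantile(ordered, k / 4) for k in (1, 2, 3)]
        lab = np.select(
            [vals <= cuts[0], vals <= cuts[1], vals <= cuts[2]],
            QUARTILE_LABELS[:3],
            default=QUARTILE_LABELS[3],
        )
        quart[mask] = lab
        median = _type1_quantile(ordered, 0.5)
        high[mask] = (vals > median).astype(float)

    quart = pd.Series(
        pd.Categorical(quart, categories=list(QUARTILE_LABELS), ordered=True),
        index=income.index,
        name="income_quartile",
    )
    high.name = "income_high"
    return pd.DataFrame({"income_quartile": quart, "income_high": high})


def _ffq_low(col: pd.Series, threshold: str) -> pd.Series:
    """1.0 iff consumption frequency is at or below ``threshold`` level."""
    known = col.dropna()
    bad = set(known.unique()) - set(FFQ_LEVELS)
    if bad:
        raise ValueError(
            f"unknown FFQ categories {sorted(bad)}; accepted labels: {list(FFQ_LEVELS)}"
        )
    rank = col.map(_FFQ_RANK)
    return pd.Series(
        np.where(col.isna(), np.nan, (rank >= _FFQ_RANK[threshold]).astype(float)),
        index=col.index,
    )


def code_risk_factors(raw: pd.DataFrame) -> pd.DataFrame:
    """Dichotomise the raw risk-factor fields.

    Expected columns (missing columns are simply skipped in the output):

    ``smoking_ever``
        already binary (current or past smoking vs never); passed through.
    ``bmi``
        numeric; obesity = BMI ≥ 30.
    ``glucose`` + ``fasting`` (0/1), ``diabetes_history`` (0/1),
    ``glucose_drugs`` (0/1)
        diabetes = fasting glucose > 125 mg/dL, or nonfasting glucose
        ≥ 200 mg/dL, or reported history, or glucose-lowering medication.
    ``ffq_fish``, ``ffq_boiled_veg``, ``ffq_raw_veg``, ``ffq_fruit``
        five-level categories (:data:`FFQ_LEVELS`); vegetables/fruit are low
        at "1-3 times/week" or less, fish is low at "1-3 times/month" or
        less.
    """
    out = pd.DataFrame(index=raw.index)
    if "smoking_ever" in raw:
        out["smoking_ever"] = raw["smoking_ever"].astype(float)
    if "bmi" in raw:
        bmi = raw["bmi"].astype(float)
        out["obesity"] = np.where(bmi.isna(), np.nan, (bmi >= 30.0).astype(float))
    if "glucose" in raw:
        glu = raw["glucose"].astype(float)
        fasting = raw["fasting"].astype(float) if "fasting" in raw else pd.Series(0.0, index=raw.index)
        hist = raw["diabetes_history"].astype(float) if "diabetes_history" in raw else pd.Series(0.0, index=raw.index)
        drugs = raw["glucose_drugs"].astype(float) if "glucose_drugs" in raw else pd.Series(0.0, index=raw.index)
        by_glucose = np.where(
            fasting == 1.0, glu > 125.0, glu >= 200.0
        )
        diab = by_glucose | (hist == 1.0) | (drugs == 1.0)
        missing = glu.isna() & ~((hist == 1.0) | (drugs == 1.0))
        out["diabetes"] = np.where(missing, np.nan, diab.astype(float))
    ffq_map = {
        "ffq_fish": ("low_fish", "1-3 times/month"),
        "ffq_boiled_veg": ("low_boiled_veg", "1-3 times/week"),
        "ffq_raw_veg": ("low_raw_veg", "1-3 times/week"),
        "ffq_fruit": ("low_fruit", "1-3 times/week"),
    }
    for col, (name, threshold) in ffq_map.items():
        if col in raw:
            out[name] = _ffq_low(raw[col], threshold)
    return out


def flc_ratio_flag(
    kappa: float | pd.Series, lam: float | pd.Series, egfr: float | pd.Series
) -> pd.Series | str:
    """Classify a serum free light chain κ/λ ratio as normal or pathological.

    The reference range is [0.26, 1.65]; with renal impairment
    (eGFR < 30 mL/min) the range widens to [0.37, 3.1]. eGFR exactly 30 uses
    the standard range (boundary inclusive upward).
    """
    k = np.asarray(kappa, dtype=float)
    l = np.asarray(lam, dtype=float)
    e = np.asarray(egfr, dtype=float)
    if np.any(l == 0):
        raise ValueError("lambda FLC must be non-zero")
    if np.any(k[~np.isnan(k)] <= 0) or np.any(l[~np.isnan(l)] < 0) or np.any(e[~np.isnan(e)] <= 0):
        raise ValueError("kappa, lambda and eGFR must be positive")
    ratio = k / l
    lo = np.where(e < 30.0, 0.37, 0.26)
    hi = np.where(e < 30.0, 3.1, 1.65)
    patho = (ratio < lo) | (ratio > hi)
    labels = np.where(patho, "pathological", "normal")
    if isinstance(kappa, pd.Series):
        return pd.Series(labels, index=kappa.index, name="flc_flag")
    return str(labels)
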