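"""Derivation of analysis covariates and effect-modifier strata.

Raw anthropometric, blood-pressure, laboratory and genetic fields are turned
into the categories used in adjustment and stratification: BMI and its WHO
bins, waist-circumference risk, hypertension and type-2-diabetes flags
(any-criterion rules with missing-propagation), Alzheimer's polygenic risk
score tertiles, APOE epsilon-4 carrier status from the rs429358/rs7412
diplotype, and the middle-aged (40-59) versus older (>= 60) age strata.

Sample-dependent categorisations (PRS tertiles) must be computed once on
the analytic sample and reused; per-row rules are idempotent.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")
WAIST_RISK_CM = {"female": 88.0, "male": 102.0}
PRS_TERTILE_LABELS = ("low", "moderate", "high")
AGE_GROUP_LABELS = ("middle", "older")


def derive_anthropometrics(
    height_m, weight_kg, waist_cm, sex
) -> pd.DataFrame:
    """BMI (kg/m^2), its category, and waist-circumference risk.

    BMI bins: underweight < 18.5, normal 18.5 to < 25, overweight 25 to
    < 30, obese >= 30. Waist is high risk at >= 88 cm (female) / >= 102 cm
    (male).
    """
    height = np.asarray(height_m, dtype=float)
    if np.any(height[np.isfinite(height)] <= 0):
        raise ValidationError("height must be positive")
    weight = np.asarray(weight_kg, dtype=float)
    bmi = weight / height**2
    category = np.select(
        [bmi < 18.5, bmi < 25, bmi < 30], BMI_CATEGORIES[:3], default="obese"
    )
    category = np.where(np.isfinite(bmi), category, None)

    sex_arr = np.asarray(sex, dtype=object)
    thresh = np.array([WAIST_RISK_CM.get(s, np.nan) for s in sex_arr])
    waist = np.asarray(waist_cm, dtype=float)
    high = waist >= thresh
    out = pd.DataFrame(
        {
            "bmi": bmi,
            "bmi_category": pd.Categorical(category, categories=BMI_CATEGORIES),
            "waist_high_risk": pd.array(
                np.where(np.isfinite(waist) & np.isfinite(thresh), high, None),
                dtype="boolean",
            ),
        }
    )
    return out


def _any_criterion(criteria: list[pd.Series]) -> pd.Series:
    """ANY-rule with missing propagation.

    True if any evaluable criterion is true, False if all evaluable
    criteria are false, missing if none is evaluable.
    """
    stacked = pd.concat([c.astype("boolean") for c in criteria], axis=1)
    any_true = stacked.fillna(False).any(axis=1)
    all_na = stacked.isna().all(axis=1)
    out = pd.array(any_true, dtype="boolean")
    out[all_na.to_numpy()] = pd.NA
    return pd.Series(out, index=stacked.index)


def derive_cardiometabolic(raw: pd.DataFrame) -> pd.DataFrame:
    """Hypertension and type-2-diabetes flags from measured and reported fields.

    Hypertension: SBP >= 140 mmHg, or DBP >= 90 mmHg, or self-reported
    history, or antihypertensive medication. T2D: medical/self-reported
    history, or glucose-lowering medication, or HbA1c >= 6.5%, or fasting
    plasma glucose >= 126 mg/dL. Each flag is true iff ANY evaluable
    criterion holds, false iff all evaluable criteria are false, and
    missing iff none is evaluable.
    """
    def col(name):
        if name in raw.columns:
            return raw[name]
        return pd.Series(pd.array([pd.NA] * len(raw), dtype="boolean"), index=raw.index)

    def ge(name, threshold):
        # numeric comparison that keeps NaN as missing rather than False
        s = col(name)
        if s.dtype == "boolean" and s.isna().all():
            return s
        out = pd.Series(
            pd.array(pd.to_numeric(s) >= threshold, dtype="boolean"), index=raw.index
        )
        out[pd.isna(s).to_numpy()] = pd.NA
        return out

    hypertension = _any_criterion(
        [
            ge("sbp", 140),
            ge("dbp", 90),
            col("hypertension_history"),
            col("antihypertensive_meds"),
        ]
    )
    t2d = _any_criterion(
        [
            col("t2d_history"),
            col("glucose_lowering_meds"),
            ge("hba1c_pct", 6.5),
            ge("fasting_glucose_mgdl", 126),
        ]
    )
    return pd.DataFrame({"hypertension": hypertension, "t2d": t2d}, index=raw.index)


def prs_tertile_cutpoints(prs) -> np.ndarray:
    """Tertile bounds of the analytic sample's PRS distribution."""
    arr = np.asarray(prs, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) < 3:
        raise ValidationError("need at least 3 PRS values for tertiles")
    return np.quantile(arr, [1 / 3, 2 / 3])


def _apoe4_from_diplotype(g429358: str, g7412: str):
    """APOE epsilon-4 carrier status from unphased genotypes.

    The epsilon-4 haplotype is rs429358-C together with rs7412-C. The
    carrier call is made whenever phase does not matter; the one genuinely
    phase-ambiguous diplotype (both SNPs heterozygous: epsilon-2/epsilon-4
    versus epsilon-1/epsilon-3) is flagged rather than guessed.

    Returns (carrier: bool | None, ambiguous: bool).
    """
    if not isinstance(g429358, str) or not isinstance(g7412, str):
        return None, False
    c1 = g429358.upper().count("C")
    c2 = g7412.upper().count("C")
    if c1 == 0:
        return False, False  # no C at rs429358 -> no epsilon-4 haplotype
    if c1 == 2:
        # both haplotypes carry rs429358-C; epsilon-4 iff any rs7412-C
        return c2 >= 1, False
    # c1 == 1
    if c2 == 2:
        return True, False  # the C-haplotype must pair with a 7412-C
    if c2 == 0:
        return False, False  # C pairs with 7412-T (epsilon-1), not epsilon-4
    return None, True  # C/T with C/T: phase-ambiguous


def derive_genetic(
    prs, rs429358, rs7412, tertile_cutpoints: np.ndarray | None = None
) -> pd.DataFrame:
    """PRS tertile and APOE4 carrier flag.

    Tertile bounds default to the supplied sample's own PRS distribution
    (compute once via :func:`prs_tertile_cutpoints` to reuse across
    subsets); ties at a bound fall into the lower tertile.
    """
    prs_arr = np.asarray(prs, dtype=float)
    if tertile_cutpoints is None:
        tertile_cutpoints = prs_tertile_cutpoints(prs_arr)
    q1, q2 = tertile_cutpoints
    tert = np.select(
        [prs_arr <= q1, prs_arr <= q2], PRS_TERTILE_LABELS[:2], default="high"
    )
    tert = np.where(np.isfinite(prs_arr), tert, None)

    calls = [_apoe4_from_diplotype(a, b) for a, b in zip(rs429358, rs7412)]
    carrier = pd.array([c for c, _ in calls], dtype="boolean")
    ambiguous = np.array([a for _, a in calls], dtype=bool)
    return pd.DataFrame(
        {
            "prs_tertile": pd.Categorical(tert, categories=PRS_TERTILE_LABELS),
            "apoe4_carrier": carrier,
            "apoe_ambiguous": ambiguous,
        }
    )


def derive_age_group(age_years) -> pd.Series:
    """Middle-aged (40-59) versus older (>= 60) stratum.

    Ages below the cohort's design range (< 40) get a missing stratum and
    trigger an out-of-design warning.
    """
    arr = np.asarray(age_years, dtype=float)
    under = np.isfinite(arr) & (arr < 40)
    if under.any():
        warnings.warn(
            f"{int(under.sum())} participant(s) younger than 40 are outside the "
            "design age range; stratum set missing",
            stacklevel=2,
        )
    group = np.where(arr >= 60, "older", np.where(arr >= 40, "middle", None))
    group = np.where(np.isfinite(arr), group, None)
    return pd.Series(pd.Categorical(group, categories=AGE_GROUP_LABELS))


def derive_all(raw: pd.DataFrame) -> pd.DataFrame:
    """Derive the full covariate block from a raw cohort table.

    Expects the raw field names produced by the synthetic generator (or an
    equivalently named extract): height_m, weight_kg, waist_cm, sex, blood
    pressures, history/medication flags, laboratory values, prs, the two
    APOE SNPs and age_baseline. Pass-through columns are kept as-is.
    """
    out = raw.copy()
    anth = derive_anthropometrics(
        raw["height_m"], raw["weight_kg"], raw["waist_cm"], raw["sex"]
    )
    anth.index = raw.index
    cardio = derive_cardiometabolic(raw)
    gen = derive_genetic(raw["prs"], raw["rs429358"], raw["rs7412"])
    gen.index = raw.index
    out = pd.concat([out, anth, cardio, gen], axis=1)
    age_group = derive_age_group(raw["age_baseline"])
    age_group.index = raw.index
    out["age_group"] = age_group
    return out
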