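"""Covariate-adjusted association analyses of DII with brain age gap.

Ordinary least squares throughout, with two adjustment sets:

* basic — age, sex, race, education, socioeconomic deprivation;
* multivariable — basic plus energy intake, BMI, smoking status, physical
  activity, cardiovascular disease, type-2 diabetes, hypertension and the
  Alzheimer's polygenic risk score.

DII enters either continuously (years of BAG per index unit) or as four
groups with group 1 (DII < -2) as reference. Confidence intervals use
t-distribution quantiles (df = n - p). Categorical covariates use
reference-cell dummy coding with references: group 1, female, white,
never-smoker, low activity, low PRS tertile, non-carrier.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import qr

from .errors import CollinearityError, ValidationError

BASIC_TERMS = ("age", "sex", "race", "education", "deprivation")
MULTI_EXTRA_TERMS = (
    "energy", "bmi", "smoking", "physical_activity", "cvd", "t2d",
    "hypertension", "prs",
)
ADJUSTMENT_SETS = {
    "basic": BASIC_TERMS,
    "multivariable": BASIC_TERMS + MULTI_EXTRA_TERMS,
}

#: term -> (raw column, kind, levels-with-reference-first)
_TERM_SPECS = {
    "age": ("age_baseline", "continuous", None),
    "age_scan": ("age_scan", "continuous", None),
    "sex": ("sex", "categorical", ("female", "male")),
    "race": ("race", "categorical", ("white", "other")),
    "education": ("education_degree", "indicator", None),
    "deprivation": ("deprivation", "continuous", None),
    "energy": ("energy_kcal", "continuous", None),
    "bmi": ("bmi", "continuous", None),
    "smoking": ("smoking", "categorical", ("never", "former", "current")),
    "physical_activity": ("physical_activity", "categorical", ("low", "moderate", "high")),
    "cvd": ("cvd", "indicator", None),
    "t2d": ("t2d", "indicator", None),
    "hypertension": ("hypertension", "indicator", None),
    "prs": ("prs", "continuous", None),
    "dii": ("dii", "continuous", None),
    "infla": ("infla", "continuous", None),
    "dii_group": ("dii_group", "categorical", (1, 2, 3, 4)),
    "age_group": ("age_group", "categorical", ("middle", "older")),
    "prs_tertile": ("prs_tertile", "categorical", ("low", "moderate", "high")),
    "apoe4": ("apoe4_carrier", "indicator", None),
    "bmi_category": ("bmi_category", "categorical",
                     ("normal", "underweight", "overweight", "obese")),
    "waist": ("waist_high_risk", "indicator", None),
    "cmd": ("cmd", "indicator", None),
}

#: covariates that must leave the adjustment set when stratifying on (or
#: interacting with) a modifier, because they are the modifier or nest it
_MODIFIER_NESTED = {
    "age_group": ("age",),
    "prs_tertile": ("prs",),
    "apoe4": (),
    "sex": ("sex",),
    "bmi_category": ("bmi",),
    "waist": (),
    "cmd": ("cvd", "t2d"),
}


def required_columns(terms) -> list[str]:
    return [_TERM_SPECS[t][0] for t in terms]


def build_design(df: pd.DataFrame, terms) -> pd.DataFrame:
    """Numeric design columns (no intercept) for the requested terms.

    Categorical terms become reference-cell dummies named
    ``term[level]``; indicator terms become 0/1 columns.
    """
    cols = {}
    for term in terms:
        raw_col, kind, levels = _TERM_SPECS[term]
        if raw_col not in df.columns:
            raise ValidationError(f"column {raw_col!r} required for term {term!r}")
        s = df[raw_col]
        if kind == "continuous":
            cols[term] = pd.to_numeric(s).astype(float)
        elif kind == "indicator":
            cols[term] = s.astype(float)
        else:
            observed = set(pd.unique(s.dropna()))
            unexpected = observed - set(levels)
            if unexpected:
                raise ValidationError(
                    f"unexpected level(s) {sorted(map(str, unexpected))} in {raw_col!r}"
                )
            for level in levels[1:]:  # first level is the reference cell
                cols[f"{term}[{level}]"] = (s == level).astype(float)
                cols[f"{term}[{level}]"][s.isna()] = np.nan
    return pd.DataFrame(cols, index=df.index)


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    _, r, piv = qr(mat, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(mat.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < mat.shape[1]:
        bad = [X.columns[i] for i in piv[rank:]]
        raise CollinearityError(f"design is rank deficient; collinear columns: {bad}")


class LinearFit:
    """An OLS fit with a tidy coefficient table."""

    def __init__(self, results, n_used, n_dropped, label, used_index=None):
        self.results = results
        self.n_used = n_used
        self.n_dropped = n_dropped
        self.label = label
        self.used_index = used_index

    def tidy(self) -> pd.DataFrame:
        res = self.results
        ci = res.conf_int()
        out = pd.DataFrame(
            {
                "term": res.params.index,
                "estimate": res.params.to_numpy(),
                "se": res.bse.to_numpy(),
                "ci_low": ci[0].to_numpy(),
                "ci_high": ci[1].to_numpy(),
                "p": res.pvalues.to_numpy(),
            }
        )
        out["n"] = self.n_used
        out["adjustment"] = self.label
        return out


def fit_linear(y: pd.Series, X: pd.DataFrame, label: str | None = None) -> LinearFit:
    """OLS of ``y`` on ``X`` plus an intercept, with listwise deletion.

    Raises :class:`CollinearityError` naming the offending columns when the
    design (including intercept) is rank deficient.
    """
    mask = y.notna() & X.notna().all(axis=1)
    yy = y.loc[mask].astype(float)
    XX = X.loc[mask].astype(float)
    if len(yy) <= XX.shape[1] + 1:
        raise ValidationError(
            f"n = {len(yy)} rows is too few for {XX.shape[1] + 1} parameters"
        )
    XX = sm.add_constant(XX, prepend=True, has_constant="raise")
    _check_rank(XX)
    results = sm.OLS(yy.to_numpy(), XX).fit()
    return LinearFit(
        results, n_used=int(len(yy)), n_dropped=int((~mask).sum()),
        label=label, used_index=yy.index,
    )


def dii_bag_association(
    cohort: pd.DataFrame,
    form: str = "continuous",
    adjustment: str = "multivariable",
    outcome: str = "bag",
    extra_terms: tuple = (),
    drop_terms: tuple = (),
) -> LinearFit:
    """Association of DII with BAG under a named adjustment set.

    ``form='continuous'`` yields one coefficient per DII unit;
    ``form='groups'`` yields contrasts of groups 2-4 versus group 1.
    ``drop_terms``/``extra_terms`` support stratified fits and sensitivity
    covariate swaps (e.g. APOE4 in place of PRS) without new code paths.
    """
    if form not in ("continuous", "groups"):
        raise ValidationError(f"unknown form {form!r}")
    if adjustment not in ADJUSTMENT_SETS:
        raise ValidationError(f"unknown adjustment set {adjustment!r}")
    exposure = "dii" if form == "continuous" else "dii_group"
    covars = [t for t in ADJUSTMENT_SETS[adjustment] if t not in drop_terms]
    terms = [exposure, *covars, *extra_terms]
    X = build_design(cohort, terms)
    return fit_linear(cohort[outcome], X, label=f"{form}/{adjustment}")


def ls_means(fit: LinearFit, design: pd.DataFrame, group_term: str = "dii_group") -> pd.DataFrame:
    """Least-squares (adjusted marginal) mean outcome per exposure group.

    For each group the fitted model is evaluated on every used row with the
    group dummies forced to that group, covariates kept at their observed
    values, and the predictions averaged. Because the model is linear this
    equals prediction at the averaged design row; the delta-method SE is
    ``sqrt(xbar' V xbar)`` with t-based confidence limits.
    """
    res = fit.results
    exog_cols = list(res.params.index)
    dummy_cols = [c for c in exog_cols if c.startswith(f"{group_term}[")]
    if not dummy_cols:
        raise ValidationError(f"fit does not include {group_term!r} dummies")
    levels_spec = _TERM_SPECS[group_term][2]
    V = res.cov_params().to_numpy()
    used = design.loc[fit.used_index] if fit.used_index is not None else design.dropna()
    base = sm.add_constant(used, prepend=True, has_constant="add")[exog_cols].copy()
    tcrit = stats.t.ppf(0.975, df=res.df_resid)

    rows = []
    for level in levels_spec:
        counterfactual = base.copy()
        for c in dummy_cols:
            counterfactual[c] = 1.0 if c == f"{group_term}[{level}]" else 0.0
        xbar = counterfactual.mean(axis=0).to_numpy()
        est = float(xbar @ res.params.to_numpy())
        se = float(np.sqrt(xbar @ V @ xbar))
        rows.append(
            {
                "group": level,
                "lsmean": est,
                "se": se,
                "ci_low": est - tcrit * se,
                "ci_high": est + tcrit * se,
            }
        )
    return pd.DataFrame(rows)


def stratified_and_interaction(
    cohort: pd.DataFrame,
    modifier: str,
    form: str = "groups",
    adjustment: str = "multivariable",
    outcome: str = "bag",
) -> dict:
    """Per-stratum DII-BAG fits plus a pooled interaction test.

    Within each stratum of the modifier the adjustment set drops the
    modifier and any covariate it nests (e.g. continuous age for the age
    strata, continuous PRS for PRS tertiles). The interaction p-value is a
    joint Wald test of all exposure-by-modifier product terms in a pooled
    model that retains the modifier main effect.
    """
    if modifier not in _MODIFIER_NESTED:
        raise ValidationError(f"unsupported modifier {modifier!r}")
    drop = _MODIFIER_NESTED[modifier] + (modifier,)

    raw_col, kind, levels = _TERM_SPECS[modifier]
    work = cohort.copy()
    if modifier == "cmd" and "cmd" not in work.columns:
        work["cmd"] = (
            work["cvd"].astype("boolean") | work["t2d"].astype("boolean")
        ).astype(float)
    mod_series = work[raw_col]
    if kind == "indicator":
        level_values = [0.0, 1.0]
        mod_values = mod_series.astype(float)
    else:
        level_values = list(levels)
        mod_values = mod_series

    strata = {}
    skipped = []
    for level in level_values:
        sub = work.loc[mod_values == level]
        if len(sub) < 50:
            skipped.append({"stratum": level, "reason": f"n = {len(sub)} too small"})
            continue
        fit = dii_bag_association(
            sub, form=form, adjustment=adjustment, outcome=outcome, drop_terms=drop
        )
        strata[level] = fit

    # pooled model with exposure x modifier product terms
    exposure = "dii" if form == "continuous" else "dii_group"
    covars = [t for t in ADJUSTMENT_SETS[adjustment] if t not in drop]
    X = build_design(work, [exposure, *covars])
    if kind == "indicator":
        mod_design = pd.DataFrame({modifier: mod_values}, index=work.index)
    else:
        mod_design = build_design(work, [modifier])
    # an empty stratum leaves an all-constant dummy; drop it (and its products)
    constant = [c for c in mod_design.columns if mod_design[c].nunique(dropna=True) <= 1]
    mod_design = mod_design.drop(columns=constant)
    if mod_design.shape[1] == 0:
        return {
            "strata": strata,
            "skipped": skipped,
            "pooled": None,
            "interaction_p": float("nan"),
            "interaction_df": 0,
        }
    expo_cols = [c for c in X.columns if c == exposure or c.startswith(f"{exposure}[")]
    products = {}
    for mc in mod_design.columns:
        for ec in expo_cols:
            products[f"{ec}:{mc}"] = X[ec] * mod_design[mc]
    pooled_X = pd.concat([X, mod_design, pd.DataFrame(products, index=work.index)], axis=1)
    pooled = fit_linear(work[outcome], pooled_X, label=f"{form}/{adjustment}+interaction")
    # joint Wald test via an explicit restriction matrix (column names carry
    # brackets/colons, so string constraints are not parseable)
    product_names = list(products)
    param_names = list(pooled.results.params.index)
    R = np.zeros((len(product_names), len(param_names)))
    for i, name in enumerate(product_names):
        R[i, param_names.index(name)] = 1.0
    wald = pooled.results.wald_test(R, scalar=True)
    return {
        "strata": strata,
        "skipped": skipped,
        "pooled": pooled,
        "interaction_p": float(wald.pvalue),
        "interaction_df": len(product_names),
    }
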