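"""Linear causal mediation of the DII-BAG association by the INFLA-score.

With linear models and no exposure-mediator interaction, the mediation
decomposition reduces to the classic product-of-coefficients form. Three
regressions on one jointly listwise-deleted row set:

1. outcome ~ exposure (+ covariates)             -> total effect (check)
2. mediator ~ exposure (+ covariates)            -> a
3. outcome ~ exposure + mediator (+ covariates)  -> c' (ADE) and b

ACME = a*b, ADE = c', total = c' + a*b, proportion mediated = ACME/total.
The identity total(model 1) = c' + a*b holds exactly on a common row set.
Inference is a nonparametric case-resampling bootstrap with percentile
confidence intervals; for linear models without interaction this estimand
coincides with the quasi-Bayesian ACME/ADE of the standard mediation
machinery, while keeping ACME + ADE = total exact on every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dii as dii_mod
from .assoc import ADJUSTMENT_SETS, build_design
from .errors import ValidationError

#: replicate totals below this magnitude are excluded from the proportion's
#: bootstrap CI (the ratio is numerically meaningless there)
DEGENERATE_TOTAL_TOL = 1e-10


@dataclass
class MediationResult:
    """Point estimates and bootstrap percentile CIs for the decomposition."""

    acme: float
    ade: float
    total: float
    prop_mediated: float
    a: float
    b: float
    ci_acme: tuple[float, float] | None = None
    ci_ade: tuple[float, float] | None = None
    ci_total: tuple[float, float] | None = None
    ci_prop: tuple[float, float] | None = None
    n: int = 0
    n_boot: int = 0
    seed: int | None = None
    n_degenerate: int = 0
    prop_ci_unstable: bool = False
    adjustment: str | None = None
    replicates: pd.DataFrame | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, est, ci in [
            ("acme", self.acme, self.ci_acme),
            ("ade", self.ade, self.ci_ade),
            ("total", self.total, self.ci_total),
            ("prop_mediated", self.prop_mediated, self.ci_prop),
        ]:
            rows.append(
                {
                    "quantity": name,
                    "estimate": est,
                    "ci_low": ci[0] if ci else np.nan,
                    "ci_high": ci[1] if ci else np.nan,
                    "n": self.n,
                    "n_boot": self.n_boot,
                    "adjustment": self.adjustment,
                }
            )
        return pd.DataFrame(rows)


def _design_matrices(
    data: pd.DataFrame, exposure: str, mediator: str, outcome: str, adjustment
):
    """Joint listwise deletion, then the two stacked design matrices."""
    covar_terms = ADJUSTMENT_SETS[adjustment] if isinstance(adjustment, str) else adjustment
    C = build_design(data, covar_terms)
    needed = pd.concat(
        [data[[exposure, mediator, outcome]].astype(float), C], axis=1
    )
    used = needed.dropna()
    if len(used) <= C.shape[1] + 3:
        raise ValidationError("too few complete rows for mediation")
    n = len(used)
    x = used[exposure].to_numpy()
    m = used[mediator].to_numpy()
    y = used[outcome].to_numpy()
    Cmat = used[C.columns].to_numpy()
    ones = np.ones((n, 1))
    X_m = np.column_stack([ones, x, Cmat])          # mediator model
    X_y = np.column_stack([ones, x, m, Cmat])       # outcome model
    return x, m, y, X_m, X_y, n


def _fit_paths(x, m, y, X_m, X_y):
    """a, b, c' from two least-squares fits (columns: const, x[, m], C)."""
    coef_m = np.linalg.lstsq(X_m, m, rcond=None)[0]
    coef_y = np.linalg.lstsq(X_y, y, rcond=None)[0]
    a = coef_m[1]
    c_prime = coef_y[1]
    b = coef_y[2]
    return a, b, c_prime


def mediation_point_estimate(
    data: pd.DataFrame,
    exposure: str = "dii",
    mediator: str = "infla",
    outcome: str = "bag",
    adjustment="multivariable",
) -> MediationResult:
    """Point decomposition of the exposure-outcome effect through the mediator."""
    x, m, y, X_m, X_y, n = _design_matrices(data, exposure, mediator, outcome, adjustment)
    a, b, c_prime = _fit_paths(x, m, y, X_m, X_y)
    acme = a * b
    total = c_prime + acme
    prop = acme / total if abs(total) > DEGENERATE_TOTAL_TOL else np.nan
    return MediationResult(
        acme=float(acme), ade=float(c_prime), total=float(total),
        prop_mediated=float(prop), a=float(a), b=float(b), n=n,
        adjustment=adjustment if isinstance(adjustment, str) else "custom",
    )


def bootstrap_mediation(
    data: pd.DataFrame,
    exposure: str = "dii",
    mediator: str = "infla",
    outcome: str = "bag",
    adjustment="multivariable",
    n_boot: int = 1000,
    seed: int = 0,
    keep_replicates: bool = False,
) -> MediationResult:
    """Case-resampling bootstrap of ACME, ADE, total effect and proportion.

    Participants are resampled with replacement; each replicate refits the
    mediator and outcome models on the same resampled rows, so
    ACME + ADE = total holds exactly replicate by replicate. CIs are
    percentile 2.5/97.5. Replicates whose |total| falls below
    ``DEGENERATE_TOTAL_TOL`` are excluded from the proportion's CI (count
    reported); if more than 10% degenerate the proportion CI is flagged
    unstable.

    ACME, ADE and the total effect keep their full-sample point estimates.
    The reported proportion mediated is the median of the replicate
    proportions — the convention of the standard mediation machinery —
    because the plug-in ratio is arbitrarily unstable whenever the total
    effect is near zero; the analytic ratio remains available from
    :func:`mediation_point_estimate`.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be at least 100")
    x, m, y, X_m, X_y, n = _design_matrices(data, exposure, mediator, outcome, adjustment)
    point = mediation_point_estimate(data, exposure, mediator, outcome, adjustment)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 29]))
    acmes = np.empty(n_boot)
    ades = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        a, b, c_prime = _fit_paths(x[idx], m[idx], y[idx], X_m[idx], X_y[idx])
        acmes[i] = a * b
        ades[i] = c_prime
    totals = acmes + ades

    ok = np.abs(totals) > DEGENERATE_TOTAL_TOL
    n_degenerate = int((~ok).sum())
    props = acmes[ok] / totals[ok]

    def ci(v):
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    point.ci_acme = ci(acmes)
    point.ci_ade = ci(ades)
    point.ci_total = ci(totals)
    point.ci_prop = ci(props) if len(props) else (np.nan, np.nan)
    point.prop_mediated = float(np.median(props)) if len(props) else float("nan")
    point.n_boot = n_boot
    point.seed = seed
    point.n_degenerate = n_degenerate
    point.prop_ci_unstable = n_degenerate > 0.1 * n_boot
    if keep_replicates:
        point.replicates = pd.DataFrame(
            {"acme": acmes, "ade": ades, "total": totals}
        )
    return point


def baseline_only_dii(
    assessments: pd.DataFrame,
    sex: pd.Series,
    reference: dii_mod.DIIReference,
    baseline_cycle: str = "baseline",
    allow_missing: bool = False,
) -> tuple[pd.DataFrame, pd.Index]:
    """DII from the first (baseline-cycle) dietary assessment only.

    Mirrors the reverse-causality guard of the mediation analysis: the
    inflammatory markers are drawn at the baseline visit, so the exposure
    is restricted to the baseline assessment. Participants without a
    plausible baseline-cycle assessment are excluded; their ids are
    returned alongside the scored table.
    """
    base = assessments.loc[assessments[dii_mod.CYCLE_COL] == baseline_cycle]
    all_ids = pd.Index(assessments[dii_mod.ID_COL].unique())
    if len(base) == 0:
        return pd.DataFrame(columns=["dii", "dii_group", "n_params_used"]), all_ids
    kept, _ = dii_mod.filter_plausible_assessments(base, sex)
    if len(kept) == 0:
        return pd.DataFrame(columns=["dii", "dii_group", "n_params_used"]), all_ids
    intake = dii_mod.average_intakes(kept)
    scores = dii_mod.compute_dii(
        intake.drop(columns=[dii_mod.ENERGY_COL], errors="ignore"),
        reference,
        allow_missing=allow_missing,
    )
    excluded = all_ids.difference(scores.index)
    return scores, excluded
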