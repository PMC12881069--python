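"""Dietary Inflammatory Index (DII) scoring.

The DII summarises the inflammatory potential of a diet. Each dietary
parameter (nutrient, bioactive compound, whole food) carries a signed
inflammatory effect weight ``w_i`` — negative for anti-inflammatory,
positive for pro-inflammatory — together with a global reference mean and
standard deviation of daily intake. A participant's intake ``x_i`` is
standardised against the global reference, mapped to a centered percentile

    c_i = 2 * Phi((x_i - mu_i) / sigma_i) - 1      in (-1, 1),

and the index is the weighted sum ``DII = sum_i c_i * w_i``. A diet at the
global mean intake of every parameter scores exactly 0, and the index is
bounded by ``sum_i |w_i|`` in absolute value.

This module also implements the quality-control steps that precede scoring
in cohort work: per-assessment energy-plausibility filtering (sex-specific
kcal bounds), averaging of intakes over a participant's repeated 24-hour
assessments, the four conventional DII groups (cut points -2, 0, +2), and
a between-assessment stability diagnostic (Pearson r and Bland-Altman
limits of agreement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ScoringError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Inclusive plausible daily-energy bounds (kcal/day) by sex. An assessment
#: is excluded only when it falls strictly outside these bounds.
ENERGY_BOUNDS_KCAL = {"female": (600.0, 3500.0), "male": (800.0, 4200.0)}

ID_COL = "participant_id"
CYCLE_COL = "cycle"
ENERGY_COL = "energy_kcal"
_NON_PARAM_COLS = (ID_COL, CYCLE_COL, ENERGY_COL)


@dataclass(frozen=True)
class DIIReference:
    """Reference table of inflammatory effect weights and global intakes.

    One row per dietary parameter with the signed effect weight and the
    global mean / standard deviation used for z-scoring intakes.
    """

    table: pd.DataFrame  # columns: name, weight, global_mean, global_sd

    def __post_init__(self) -> None:
        required = {"name", "weight", "global_mean", "global_sd"}
        missing = required - set(self.table.columns)
        if missing:
            raise SchemaError(f"reference table missing columns: {sorted(missing)}")
        if len(self.table) < 1:
            raise ValidationError("reference table must have at least one parameter")
        if self.table["name"].duplicated().any():
            dupes = self.table.loc[self.table["name"].duplicated(), "name"].tolist()
            raise ValidationError(f"duplicate parameter names in reference: {dupes}")
        if not (self.table["global_sd"] > 0).all():
            bad = self.table.loc[~(self.table["global_sd"] > 0), "name"].tolist()
            raise ValidationError(f"non-positive global SD for parameters: {bad}")

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    @property
    def weights(self) -> pd.Series:
        return self.table.set_index("name")["weight"]

    @property
    def abs_weight_sum(self) -> float:
        """Analytic bound on |DII|: the sum of absolute effect weights."""
        return float(self.table["weight"].abs().sum())

    @classmethod
    def from_csv(cls, path) -> "DIIReference":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def filter_plausible_assessments(
    assessments: pd.DataFrame, sex: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop dietary assessments with implausible energy intake.

    An assessment is kept iff its energy lies within [600, 3500] kcal/day for
    females or [800, 4200] for males, bounds inclusive. A participant is
    flagged excluded iff none of their assessments survive.

    Parameters
    ----------
    assessments
        One row per (participant, assessment) with at least
        ``participant_id`` and ``energy_kcal`` columns.
    sex
        Sex per participant ('female'/'male'), indexed by participant id.

    Returns
    -------
    (kept, report)
        ``kept`` is the surviving subset of ``assessments``; ``report`` has
        one row per participant with ``n_total``, ``n_kept`` and
        ``excluded`` columns.
    """
    if ID_COL not in assessments.columns or ENERGY_COL not in assessments.columns:
        raise SchemaError(f"assessments must have {ID_COL!r} and {ENERGY_COL!r} columns")
    row_sex = assessments[ID_COL].map(sex)
    unknown = ~row_sex.isin(ENERGY_BOUNDS_KCAL)
    if unknown.any():
        bad = assessments.loc[unknown, ID_COL].unique().tolist()
        raise ValidationError(f"unknown or missing sex code for participants: {bad[:10]}")
    lo = row_sex.map({s: b[0] for s, b in ENERGY_BOUNDS_KCAL.items()})
    hi = row_sex.map({s: b[1] for s, b in ENERGY_BOUNDS_KCAL.items()})
    keep = (assessments[ENERGY_COL] >= lo) & (assessments[ENERGY_COL] <= hi)
    kept = assessments.loc[keep].copy()

    n_total = assessments.groupby(ID_COL).size()
    n_kept = kept.groupby(ID_COL).size().reindex(n_total.index, fill_value=0)
    report = pd.DataFrame(
        {
            ID_COL: n_total.index,
            "n_total": n_total.to_numpy(),
            "n_kept": n_kept.to_numpy(),
            "excluded": (n_kept == 0).to_numpy(),
        }
    ).reset_index(drop=True)
    return kept, report


def average_intakes(kept: pd.DataFrame) -> pd.DataFrame:
    """Average each parameter (and energy) over a participant's kept assessments.

    Every participant present must have at least one kept assessment;
    participants with zero plausible assessments are excluded upstream by
    :func:`filter_plausible_assessments`.
    """
    if len(kept) == 0:
        raise ValidationError("no assessments to average")
    value_cols = [c for c in kept.columns if c != CYCLE_COL and c != ID_COL]
    return kept.groupby(ID_COL)[value_cols].mean()


def compute_dii(
    intake: pd.DataFrame,
    reference: DIIReference,
    allow_missing: bool = False,
    return_contributions: bool = False,
):
    """Score diets against a DII reference table.

    ``intake`` holds per-participant mean daily intakes (participants in
    rows, parameters in columns). Parameters present in the reference but
    absent from ``intake`` abort scoring unless ``allow_missing`` is set,
    in which case the available subset is scored without re-weighting and
    the absent parameters are logged (mirroring scoring on 31 of the 45
    published parameters).

    Returns a DataFrame with ``dii``, ``dii_group`` and ``n_params_used``;
    with ``return_contributions=True`` a second DataFrame of per-parameter
    contributions ``c_i * w_i`` is returned as well.
    """
    if isinstance(intake, pd.Series):
        intake = intake.to_frame().T
    ref = reference.table.set_index("name")
    present = [n for n in ref.index if n in intake.columns]
    absent = [n for n in ref.index if n not in intake.columns]
    if absent:
        if not allow_missing:
            raise ScoringError(
                f"intake is missing {len(absent)} reference parameters "
                f"(e.g. {absent[:5]}); pass allow_missing=True to score a subset"
            )
        logger.warning(
            "scoring %d of %d reference parameters; absent: %s",
            len(present), len(ref), absent,
        )
    if not present:
        raise ScoringError("no reference parameters present in intake table")

    x = intake[present].to_numpy(dtype=float)
    mu = ref.loc[present, "global_mean"].to_numpy()
    sd = ref.loc[present, "global_sd"].to_numpy()
    w = ref.loc[present, "weight"].to_numpy()
    z = (x - mu) / sd
    centered_pct = 2.0 * stats.norm.cdf(z) - 1.0
    contrib = centered_pct * w
    dii = contrib.sum(axis=1)

    out = pd.DataFrame(
        {
            "dii": dii,
            "dii_group": assign_dii_group(dii),
            "n_params_used": len(present),
        },
        index=intake.index,
    )
    if return_contributions:
        return out, pd.DataFrame(contrib, index=intake.index, columns=present)
    return out


def assign_dii_group(dii):
    """Map DII values onto the four conventional groups.

    Group 1: DII < -2; group 2: -2 <= DII < 0; group 3: 0 <= DII < 2;
    group 4: DII >= 2. The groups partition the real line.
    """
    arr = np.asarray(dii, dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("DII values must be finite to assign groups")
    groups = np.select([arr < -2, arr < 0, arr < 2], [1, 2, 3], default=4)
    if np.isscalar(dii) or arr.ndim == 0:
        return int(groups)
    return groups


def dii_stability(first_scores, later_scores) -> dict:
    """Between-assessment stability of DII scores.

    Pearson correlation plus Bland-Altman mean difference and 95% limits of
    agreement (mean difference +/- 1.96 * SD of paired differences) between
    scores from an earlier and a later set of assessments.
    """
    a = np.asarray(first_scores, dtype=float)
    b = np.asarray(later_scores, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired score vectors must have equal length")
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if len(a) < 3:
        raise InsufficientDataError("need at least 3 complete pairs")
    diffs = a - b
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    if a.std() == 0 or b.std() == 0:
        r, p = float("nan"), float("nan")
        r_defined = False
    else:
        r, p = stats.pearsonr(a, b)
        r_defined = True
    return {
        "n": int(len(a)),
        "pearson_r": float(r),
        "pearson_p": float(p),
        "r_defined": r_defined,
        "mean_difference": mean_diff,
        "loa_lower": mean_diff - 1.96 * sd_diff,
        "loa_upper": mean_diff + 1.96 * sd_diff,
    }
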