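"""INFLA-score: a decile-based composite of low-grade systemic inflammation.

Four blood markers enter the composite: high-sensitivity C-reactive protein
(mg/L), white blood cell count (10^9/L), platelet count (10^9/L), and the
neutrophil-to-lymphocyte ratio. For each marker, a value in the 7th-10th
decile of the reference distribution scores +1..+4 and a value in the
1st-4th decile scores -4..-1; the middle deciles (5th, 6th) score 0 — an
inference forced by the published -16..+16 range. The INFLA-score is the
sum of the four marker scores; higher scores indicate more inflammation.

Decile rank for a value v is the smallest k with v <= cutpoint_k (else 10),
so ties at a cut point fall into the lower decile. Because scoring depends
on marker values only through ranks, any monotone transformation applied to
a whole marker column leaves the composite unchanged.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError

MARKERS = ("crp", "wbc", "platelets", "nlr")
#: Decile rank -> integer score. Forced by the published -16..+16 range.
_RANK_SCORE = {1: -4, 2: -3, 3: -2, 4: -1, 5: 0, 6: 0, 7: 1, 8: 2, 9: 3, 10: 4}


def compute_nlr(neutrophils, lymphocytes):
    """Neutrophil-to-lymphocyte ratio.

    Scalars with non-positive lymphocytes raise; in array form the ratio is
    set missing (NaN) for those rows so the participant's INFLA-score ends
    up missing rather than infinite.
    """
    if np.isscalar(neutrophils) and np.isscalar(lymphocytes):
        if lymphocytes <= 0:
            raise ValidationError("lymphocyte count must be positive for the ratio")
        return neutrophils / lymphocytes
    neut = np.asarray(neutrophils, dtype=float)
    lymph = np.asarray(lymphocytes, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lymph > 0, neut / lymph, np.nan)
    return ratio


def decile_cutpoints(values) -> np.ndarray:
    """10th..90th percentiles of the non-missing values (9 monotone cuts)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) < 10:
        raise InsufficientDataError(
            f"need at least 10 non-missing values for decile cut points, got {len(arr)}"
        )
    return np.percentile(arr, np.arange(10, 100, 10))


def decile_rank(value, cutpoints) -> np.ndarray:
    """Decile rank in 1..10; smallest k with value <= cutpoint_k, else 10."""
    cuts = np.asarray(cutpoints, dtype=float)
    if len(cuts) != 9 or np.any(np.diff(cuts) < 0):
        raise ValidationError("cutpoints must be 9 non-decreasing values")
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    rank = np.searchsorted(cuts, arr, side="left") + 1
    return rank.astype(float)


def score_marker(value, cutpoints):
    """Integer score for a marker value given the reference decile cuts.

    Deciles 1-4 score -4..-1, deciles 5-6 score 0, deciles 7-10 score
    +1..+4. Non-finite values yield a missing (NaN) score.
    """
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    rank = decile_rank(arr, cutpoints)
    score = np.full(arr.shape, np.nan)
    finite = np.isfinite(arr)
    r = rank[finite]
    # ranks 1..4 -> r-5 (i.e. -4..-1); 5,6 -> 0; 7..10 -> r-6 (i.e. +1..+4)
    score[finite] = np.where(r <= 4, r - 5, np.where(r >= 7, r - 6, 0.0))
    if np.isscalar(value):
        return float(score[0])
    return score


def compute_infla(
    markers: pd.DataFrame, cutpoints: dict[str, np.ndarray] | None = None
) -> pd.DataFrame:
    """INFLA-score per participant from the four-marker table.

    ``markers`` needs columns ``crp``, ``wbc``, ``platelets`` and either
    ``nlr`` or both ``neutrophils`` and ``lymphocytes``. Decile cut points
    default to the analysis sample itself; pass ``cutpoints`` (marker ->
    9 values) to score against an external reference instead.

    Returns a DataFrame (index preserved) with per-marker scores, the total
    ``infla`` (NaN when any component is missing) and the per-marker decile
    ranks. The number of participants with missing INFLA is stored in
    ``result.attrs['n_missing']``.
    """
    df = markers.copy()
    if "nlr" not in df.columns:
        if not {"neutrophils", "lymphocytes"} <= set(df.columns):
            raise ValidationError(
                "markers need an 'nlr' column or both 'neutrophils' and 'lymphocytes'"
            )
        df["nlr"] = compute_nlr(df["neutrophils"], df["lymphocytes"])
    missing_cols = [m for m in MARKERS if m not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing marker columns: {missing_cols}")

    if cutpoints is None:
        cutpoints = {m: decile_cutpoints(df[m]) for m in MARKERS}

    out = pd.DataFrame(index=df.index)
    for m in MARKERS:
        out[f"{m}_decile"] = decile_rank(df[m].to_numpy(), cutpoints[m])
        out.loc[~np.isfinite(df[m].to_numpy(dtype=float)), f"{m}_decile"] = np.nan
        out[f"{m}_score"] = score_marker(df[m].to_numpy(), cutpoints[m])
    score_cols = [f"{m}_score" for m in MARKERS]
    out["infla"] = out[score_cols].sum(axis=1, skipna=False)
    out.attrs["n_missing"] = int(out["infla"].isna().sum())
    return out


def cutpoints_to_json(cutpoints: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        json.dump({m: list(map(float, c)) for m, c in cutpoints.items()}, fh, indent=2)


def cutpoints_from_json(path) -> dict[str, np.ndarray]:
    with open(path) as fh:
        raw = json.load(fh)
    return {m: np.asarray(c, dtype=float) for m, c in raw.items()}
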