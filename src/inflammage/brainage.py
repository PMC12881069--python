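"""Brain-age estimation from imaging-derived phenotypes (IDPs).

Workflow
--------
1. Keep complete-case rows only (any missing IDP excludes the row; the
   count is reported).
2. Select a healthy reference subset — participants free of stroke, type-2
   diabetes, long-term illness/disability/frailty and fair-or-poor
   self-rated health — in whom brain age should track chronological age.
3. Randomly split the healthy subset 4:1 into training and validation.
4. Z-score every IDP using means/SDs computed from the *training rows
   only* and apply those constants everywhere (no leakage).
5. Fit a small model zoo (L1-penalised linear regression, gradient-boosted
   trees, support-vector regression; each with or without recursive
   feature elimination) with a bounded, seeded hyperparameter search, and
   keep the model with the lowest validation mean absolute error.
6. Regress raw training predictions on chronological age to obtain the
   bias slope alpha and intercept beta, and correct every prediction as
   ``corrected = (raw - beta) / alpha``. Brain-age models over-predict in
   the young and under-predict in the old; this linear re-calibration makes
   corrected-on-chronological regression slope 1 / intercept 0 on training.
7. Brain age gap: BAG = corrected brain age - chronological age at scan
   (positive = older-looking brain).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFECV
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import RandomizedSearchCV
from sklearn.svm import SVR

from .errors import InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

HEALTHY_EXCLUSION_FLAGS = (
    "stroke",
    "t2d_history",
    "longstanding_illness",
    "poor_self_rated_health",
)

MODEL_NAMES = ("lasso", "gbt", "svr")
FEATURE_SELECTIONS = ("none", "rfecv")


@dataclass
class BrainAgeModel:
    """A fitted brain-age predictor plus everything needed to apply it."""

    estimator: object
    model_name: str
    feature_selection: str
    columns: list[str]                 # IDP columns after zero-SD drops
    support: np.ndarray                # bool mask over `columns`
    means: pd.Series                   # training-derived standardisation constants
    sds: pd.Series
    validation_mae: float
    mae_table: pd.DataFrame
    n_nonzero_coef: int | None = None
    bias_alpha: float | None = None
    bias_beta: float | None = None
    dropped_columns: list[str] = field(default_factory=list)

    def predict_raw(self, idps: pd.DataFrame) -> np.ndarray:
        """Predict (uncorrected) brain age for rows of an unstandardised IDP table."""
        x = (idps[self.columns] - self.means) / self.sds
        return np.asarray(self.estimator.predict(x.to_numpy()[:, self.support]))

    def predict_corrected(self, idps: pd.DataFrame) -> np.ndarray:
        if self.bias_alpha is None:
            raise ValidationError("bias correction has not been fitted")
        return apply_bias_correction(self.predict_raw(idps), self.bias_alpha, self.bias_beta)

    def to_json(self, path) -> None:
        """Persist a linear model portably (coefficients + constants)."""
        if not hasattr(self.estimator, "coef_") or self.model_name != "lasso":
            raise ValidationError(
                "only linear models are persisted as JSON; re-fit tree/SVR models "
                "from the run configuration instead"
            )
        payload = {
            "model_name": self.model_name,
            "feature_selection": self.feature_selection,
            "columns": self.columns,
            "support": self.support.astype(int).tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "coef": np.asarray(self.estimator.coef_).tolist(),
            "intercept": float(self.estimator.intercept_),
            "validation_mae": self.validation_mae,
            "bias_alpha": self.bias_alpha,
            "bias_beta": self.bias_beta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def select_healthy_subset(cohort: pd.DataFrame) -> tuple[pd.Index, dict]:
    """Participants free of the healthy-subset exclusion conditions.

    A participant is healthy iff every exclusion flag is present and False;
    a missing flag excludes conservatively. Returns (ids, counts).
    """
    missing_cols = [c for c in HEALTHY_EXCLUSION_FLAGS if c not in cohort.columns]
    if missing_cols:
        raise ValidationError(f"cohort lacks health flags: {missing_cols}")
    flags = cohort[list(HEALTHY_EXCLUSION_FLAGS)].astype("boolean")
    any_missing = flags.isna().any(axis=1)
    any_true = (flags == True).any(axis=1)  # noqa: E712 — NA-safe comparison
    healthy = (~any_true & ~any_missing).to_numpy()
    counts = {
        "n_total": int(len(cohort)),
        "n_healthy": int(healthy.sum()),
        "n_excluded_missing_flag": int((any_missing & ~any_true).sum()),
    }
    for c in HEALTHY_EXCLUSION_FLAGS:
        counts[f"n_{c}"] = int((flags[c] == True).sum())  # noqa: E712
    return cohort.index[healthy], counts


def split_train_validation(ids, seed: int, train_frac: float = 0.8):
    """Seeded 4:1 split into training and validation id sets.

    The training size is round-half-away-from-zero of ``train_frac * n``
    (4,355 ids -> 3,484 / 871). Deterministic given (ids, seed) regardless
    of the incoming order.
    """
    ids = np.asarray(sorted(ids))
    n = len(ids)
    if n < 5:
        raise InsufficientDataError(f"need at least 5 ids to split 4:1, got {n}")
    n_train = int(np.floor(train_frac * n + 0.5))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    perm = rng.permutation(n)
    return ids[perm[:n_train]], ids[perm[n_train:]]


def standardize_idps(idps: pd.DataFrame, train_ids):
    """Z-score all rows using training-row means and SDs only.

    Columns with zero training SD are dropped with a logged warning rather
    than silently imputed. Returns (standardised table, constants frame
    with 'mean'/'sd' columns, dropped column list).
    """
    train = idps.loc[train_ids]
    means = train.mean()
    sds = train.std(ddof=0)
    dropped = sds.index[sds == 0].tolist()
    if dropped:
        logger.warning("dropping %d IDP column(s) with zero training SD: %s",
                       len(dropped), dropped[:5])
    keep = [c for c in idps.columns if c not in dropped]
    std = (idps[keep] - means[keep]) / sds[keep]
    constants = pd.DataFrame({"mean": means[keep], "sd": sds[keep]})
    return std, constants, dropped


def _candidate_models(seed: int, n_iter: int, cv: int):
    """The bounded, seeded hyperparameter search for each predictor kind."""
    rng_seed = int(seed) % (2**31 - 1)
    lasso = LassoCV(alphas=np.logspace(-3, 0, 4), cv=cv, max_iter=20000)

    import xgboost as xgb

    gbt = RandomizedSearchCV(
        xgb.XGBRegressor(
            objective="reg:squarederror", random_state=rng_seed,
            n_jobs=1, verbosity=0, tree_method="hist",
        ),
        param_distributions={
            "n_estimators": [100, 200, 300],
            "max_depth": [2, 3, 4],
            "learning_rate": [0.03, 0.1, 0.2],
            "subsample": [0.7, 1.0],
        },
        n_iter=n_iter, cv=cv, random_state=rng_seed,
        scoring="neg_mean_absolute_error", n_jobs=1,
    )
    svr = RandomizedSearchCV(
        SVR(kernel="rbf"),
        param_distributions={
            "C": [1.0, 10.0, 100.0],
            "gamma": ["scale", 0.01, 0.001],
            "epsilon": [0.1, 0.5, 1.0],
        },
        n_iter=n_iter, cv=cv, random_state=rng_seed,
        scoring="neg_mean_absolute_error", n_jobs=1,
    )
    return {"lasso": lasso, "gbt": gbt, "svr": svr}


def train_and_select(
    x_train: pd.DataFrame,
    y_train,
    x_val: pd.DataFrame,
    y_val,
    grid: str | list[tuple[str, str]] = "lasso",
    seed: int = 0,
    cv: int = 3,
    n_iter: int = 6,
    means: pd.Series | None = None,
    sds: pd.Series | None = None,
) -> BrainAgeModel:
    """Fit the model grid on training data and pick the lowest validation MAE.

    ``grid`` is ``"lasso"`` (the single L1-linear cell, the default for
    large runs), ``"full"`` (3 predictors x 2 feature-selection modes), or
    an explicit list of (model, feature_selection) pairs. Hyperparameters
    are tuned with training-internal cross-validation; the cells are then
    compared on raw validation-set MAE. Standardised inputs are expected
    (pass ``means``/``sds`` so the returned model can score raw tables).
    """
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if np.var(y_train) == 0:
        raise ValidationError("training label (age) has zero variance")
    if isinstance(grid, str):
        if grid == "lasso":
            cells = [("lasso", "none")]
        elif grid == "full":
            cells = [(m, fs) for fs in FEATURE_SELECTIONS for m in MODEL_NAMES]
        else:
            raise ValidationError(f"unknown grid {grid!r}")
    else:
        cells = list(grid)

    columns = list(x_train.columns)
    xt = x_train.to_numpy(dtype=float)
    xv = x_val.to_numpy(dtype=float)

    supports: dict[str, np.ndarray] = {"none": np.ones(len(columns), dtype=bool)}
    if any(fs == "rfecv" for _, fs in cells):
        # One shared L1-linear feature ranking (SVR-rbf has no importances).
        selector = RFECV(
            Lasso(alpha=0.01, max_iter=20000), step=0.2, cv=cv,
            min_features_to_select=min(10, len(columns)),
        )
        selector.fit(xt, y_train)
        supports["rfecv"] = selector.support_

    rows = []
    fitted = {}
    for model_name, fs in cells:
        mask = supports[fs]
        est = _candidate_models(seed, n_iter, cv)[model_name]
        est.fit(xt[:, mask], y_train)
        if hasattr(est, "best_estimator_"):
            est = est.best_estimator_
        pred_val = est.predict(xv[:, mask])
        mae = float(np.mean(np.abs(pred_val - y_val)))
        n_nonzero = int(np.sum(est.coef_ != 0)) if hasattr(est, "coef_") else None
        rows.append(
            {
                "model": model_name,
                "feature_selection": fs,
                "validation_mae": mae,
                "n_features": int(mask.sum()),
                "n_nonzero_coef": n_nonzero,
            }
        )
        fitted[(model_name, fs)] = est
        logger.info("grid cell %s/%s: validation MAE %.3f y", model_name, fs, mae)

    mae_table = pd.DataFrame(rows)
    best_idx = int(mae_table["validation_mae"].idxmin())
    best = mae_table.loc[best_idx]
    key = (best["model"], best["feature_selection"])
    if means is None:
        means = pd.Series(0.0, index=columns)
        sds = pd.Series(1.0, index=columns)
    return BrainAgeModel(
        estimator=fitted[key],
        model_name=best["model"],
        feature_selection=best["feature_selection"],
        columns=columns,
        support=supports[best["feature_selection"]],
        means=means.loc[columns],
        sds=sds.loc[columns],
        validation_mae=float(best["validation_mae"]),
        mae_table=mae_table,
        n_nonzero_coef=best["n_nonzero_coef"],
    )


def fit_bias_correction(predictions, ages) -> tuple[float, float]:
    """Least-squares slope/intercept of predicted-on-chronological age.

    Fitted on the training set only. Refuses a slope within 1e-8 of zero
    (the correction would divide by ~0).
    """
    pred = np.asarray(predictions, dtype=float)
    age = np.asarray(ages, dtype=float)
    if len(pred) < 3:
        raise InsufficientDataError("need at least 3 training points")
    if np.var(age) == 0:
        raise ValidationError("chronological age has zero variance")
    alpha, beta = np.polyfit(age, pred, 1)
    if abs(alpha) < 1e-8:
        raise ValidationError("bias slope is numerically zero; correction refused")
    return float(alpha), float(beta)


def apply_bias_correction(raw_predictions, alpha: float, beta: float):
    """Corrected brain age = (raw - beta) / alpha."""
    if alpha == 0:
        raise ValidationError("bias slope alpha must be nonzero")
    return (np.asarray(raw_predictions, dtype=float) - beta) / alpha


def compute_bag(corrected, age_at_scan, participant_ids=None) -> pd.DataFrame:
    """BAG = corrected brain age - chronological age at scan (years)."""
    corrected = np.asarray(corrected, dtype=float)
    age = np.asarray(age_at_scan, dtype=float)
    if np.any(age[np.isfinite(age)] <= 0):
        raise ValidationError("ages must be positive")
    out = pd.DataFrame(
        {
            "corrected_brain_age": corrected,
            "age_scan": age,
            "bag": corrected - age,
        }
    )
    if participant_ids is not None:
        out.insert(0, "participant_id", np.asarray(participant_ids))
    return out


def estimate_brain_age_gap(
    idps: pd.DataFrame,
    cohort: pd.DataFrame,
    grid: str | list = "lasso",
    seed: int = 0,
    age_col: str = "age_scan",
) -> tuple[pd.DataFrame, BrainAgeModel, dict]:
    """End-to-end brain-age workflow on an IDP table + cohort table.

    ``idps`` is indexed by participant id; ``cohort`` (same index) provides
    chronological age at scan and the healthy-subset flags. Returns the
    per-participant BAG table (complete-case rows), the selected model with
    its bias correction, and an info dict with exclusion counts.
    """
    common = idps.index.intersection(cohort.index)
    idps = idps.loc[common]
    cohort = cohort.loc[common]

    complete = idps.notna().all(axis=1)
    n_incomplete = int((~complete).sum())
    idps = idps.loc[complete]
    cohort_cc = cohort.loc[complete]

    healthy_ids, healthy_counts = select_healthy_subset(cohort_cc)
    train_ids, val_ids = split_train_validation(healthy_ids, seed=seed)

    std, constants, dropped = standardize_idps(idps, train_ids)
    age = cohort_cc[age_col].astype(float)

    model = train_and_select(
        std.loc[train_ids], age.loc[train_ids],
        std.loc[val_ids], age.loc[val_ids],
        grid=grid, seed=seed,
        means=constants["mean"], sds=constants["sd"],
    )
    model.dropped_columns = dropped

    pred_train = model.estimator.predict(
        std.loc[train_ids].to_numpy()[:, model.support]
    )
    alpha, beta = fit_bias_correction(pred_train, age.loc[train_ids])
    model.bias_alpha, model.bias_beta = alpha, beta

    raw_all = model.estimator.predict(std.to_numpy()[:, model.support])
    corrected = apply_bias_correction(raw_all, alpha, beta)
    bag = compute_bag(corrected, age.to_numpy(), participant_ids=std.index)
    bag["raw_brain_age"] = raw_all
    bag = bag.set_index("participant_id")

    info = {
        "n_input": int(len(common)),
        "n_incomplete_idp_excluded": n_incomplete,
        "n_train": int(len(train_ids)),
        "n_validation": int(len(val_ids)),
        "n_test": int(len(idps) - len(train_ids) - len(val_ids)),
        "validation_mae": model.validation_mae,
        "bias_alpha": alpha,
        "bias_beta": beta,
        **healthy_counts,
    }
    return bag, model, info
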