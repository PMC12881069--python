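"""Synthetic cohort generator with known diet-inflammation-brain-age structure.

Cohort studies linking dietary inflammatory potential to brain aging rest
on access-controlled data, so every stage of this package is exercised on
simulated cohorts whose estimands are known by construction:

* nutrient intakes are log-normal around a global reference, tied together
  by a latent "diet inflammatory tendency" factor aligned with the signs of
  the inflammatory effect weights, so the realised DII spans roughly the
  -6..+5 range seen in large cohorts;
* four inflammatory blood markers share a latent inflammation factor that
  depends linearly on the realised DII (and on adiposity and smoking);
* the brain age gap (BAG) is a linear combination of a direct DII effect,
  an INFLA-score-mediated effect calibrated so that ACME/total equals
  ``prop_mediated_true``, covariate effects, optional DII-group and
  age-stratum shifts, and Gaussian noise (default SD 4 years, a typical
  brain-age residual scale);
* imaging-derived phenotypes (IDPs) are noisy linear readouts of true brain
  age (= age at scan + true BAG), so the brain-age model has a learnable
  age signal.

Ground truth (true DII, latent inflammation, true BAG, realised effect
parameters) is returned separately from the observable tables and must
never be fed to the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dii as dii_mod
from . import infla as infla_mod
from .errors import SchemaError, ValidationError

#: printed modality sizes of the full-scale IDP battery (sums to 1,079)
FULL_SCALE_MODALITIES = {
    "T1": 165,
    "T2_FLAIR": 1,
    "T2star": 14,
    "dMRI": 675,
    "rsfMRI": 210,
    "taskfMRI": 14,
}

ASSESSMENT_CYCLES = ("baseline", "online1", "online2", "online3", "online4")

TRUTH_COLUMNS = ("true_dii", "true_infla_latent", "true_bag", "true_brain_age")


def scale_modalities(n_idps: int) -> dict[str, int]:
    """Scale the full-scale modality proportions to ``n_idps`` columns.

    Largest-remainder apportionment, so the counts always sum to
    ``n_idps`` exactly.
    """
    total = sum(FULL_SCALE_MODALITIES.values())
    raw = {m: n_idps * c / total for m, c in FULL_SCALE_MODALITIES.items()}
    floors = {m: int(np.floor(v)) for m, v in raw.items()}
    shortfall = n_idps - sum(floors.values())
    order = sorted(raw, key=lambda m: raw[m] - floors[m], reverse=True)
    for m in order[:shortfall]:
        floors[m] += 1
    return floors


@dataclass
class SimulationConfig:
    """Everything the generator needs; the defaults are the study conditions.

    ``beta_dii_bag`` is the *total* (direct + mediated) BAG effect in years
    per DII unit; ``prop_mediated_true`` is the fraction of it carried by
    the inflammation path. ``group_bag_effects`` and
    ``age_group_bag_effects`` add BAG shifts keyed by realised DII group
    (and baseline-age stratum), for studies of group contrasts and
    effect-modification.
    """

    n_participants: int
    seed: int = 0
    n_idps: int = 200
    idp_modality_counts: dict[str, int] | None = None
    beta_dii_bag: float = 0.07
    prop_mediated_true: float = 0.08
    group_bag_effects: dict[int, float] | None = None
    age_group_bag_effects: dict[str, dict[int, float]] | None = None
    idp_age_loading_range: tuple[float, float] = (0.4, 1.2)
    idp_noise_sd: float = 5.0
    bag_noise_sd: float = 4.0
    nutrient_sd_log: float = 0.30
    within_person_sd_log: float = 0.25
    diet_inflammatory_loading: float = 0.28
    infla_per_dii: float = 0.045  # latent inflammation (SD units) per DII unit
    frac_female: float = 0.536
    age_range_baseline: tuple[float, float] = (40.0, 70.0)
    scan_lag_mean_sd: tuple[float, float] = (8.7, 1.5)
    frac_baseline_assessment: float = 0.21
    assessment_count_probs: tuple[float, ...] = (0.29, 0.27, 0.22, 0.14, 0.08)
    missingness_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValidationError("n_participants must be at least 1")
        # normalise YAML/JSON round-tripped configs (list tuples, str keys)
        for name in ("idp_age_loading_range", "age_range_baseline",
                     "scan_lag_mean_sd", "assessment_count_probs"):
            value = getattr(self, name)
            if isinstance(value, list):
                setattr(self, name, tuple(value))
        if self.group_bag_effects:
            self.group_bag_effects = {
                int(k): float(v) for k, v in self.group_bag_effects.items()
            }
        if self.age_group_bag_effects:
            self.age_group_bag_effects = {
                str(s): {int(k): float(v) for k, v in d.items()}
                for s, d in self.age_group_bag_effects.items()
            }
        if not 0 <= self.prop_mediated_true <= 1:
            raise ValidationError("prop_mediated_true must lie in [0, 1]")
        if self.idp_modality_counts is None:
            self.idp_modality_counts = scale_modalities(self.n_idps)
        if sum(self.idp_modality_counts.values()) != self.n_idps:
            raise ValidationError(
                "idp_modality_counts must sum to n_idps "
                f"({sum(self.idp_modality_counts.values())} != {self.n_idps})"
            )
        if abs(sum(self.assessment_count_probs) - 1) > 1e-9:
            raise ValidationError("assessment_count_probs must sum to 1")
        if not 0 <= self.frac_female <= 1:
            raise ValidationError("frac_female must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth, kept apart from the observable tables.

    ``participants`` has one row per participant with the true DII, the
    latent inflammation factor, the true BAG and the true brain age
    (= age at scan + true BAG, exactly). ``params`` records the realised
    effect parameters; ``idp_loadings`` is filled by :func:`generate_idps`.
    """

    participants: pd.DataFrame
    params: dict
    idp_loadings: pd.Series | None = None


@dataclass
class IDPMatrix:
    """Participants x imaging features, with a modality label per column."""

    data: pd.DataFrame
    modalities: dict[str, str]  # column -> modality


@dataclass
class SimulatedCohort:
    reference: dii_mod.DIIReference
    dietary_assessments: pd.DataFrame
    blood_markers: pd.DataFrame
    covariates: pd.DataFrame
    idps: IDPMatrix
    truth: SyntheticTruth


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def generate_reference(n_params: int, seed: int) -> dii_mod.DIIReference:
    """A reproducible stand-in DII reference table (synthetic weights).

    Signed effect weights with both pro- and anti-inflammatory parameters
    (when ``n_params >= 2``), positive global means spanning typical
    nutrient scales, and positive global SDs. Published weights are a
    drop-in CSV with the same schema.
    """
    if n_params < 1:
        raise ValidationError("n_params must be at least 1")
    rng = _rng(seed, 0)
    magnitudes = rng.uniform(0.05, 0.75, n_params)
    signs = np.where(rng.random(n_params) < 0.55, -1.0, 1.0)
    if n_params >= 2:
        signs[0], signs[1] = 1.0, -1.0  # guarantee a sign mixture
    means = np.exp(rng.uniform(np.log(0.5), np.log(500.0), n_params))
    cv = rng.uniform(0.25, 0.6, n_params)
    table = pd.DataFrame(
        {
            "name": [f"param_{i + 1:02d}" for i in range(n_params)],
            "weight": magnitudes * signs,
            "global_mean": means,
            "global_sd": means * cv,
        }
    )
    return dii_mod.DIIReference(table)


def _draw_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_participants
    ids = [f"P{i + 1:06d}" for i in range(n)]
    sex = np.where(rng.random(n) < config.frac_female, "female", "male")
    female = sex == "female"
    lo, hi = config.age_range_baseline
    age_baseline = rng.uniform(lo, hi, n)
    lag_mu, lag_sd = config.scan_lag_mean_sd
    age_scan = age_baseline + rng.normal(lag_mu, lag_sd, n)

    education_degree = rng.random(n) < 0.51
    race = np.where(rng.random(n) < 0.93, "white", "other")
    deprivation = rng.normal(-1.9, 2.7, n)
    smoking = rng.choice(["never", "former", "current"], size=n, p=[0.61, 0.33, 0.06])
    activity = rng.choice(["low", "moderate", "high"], size=n, p=[0.16, 0.46, 0.38])

    height = np.where(female, rng.normal(1.63, 0.07, n), rng.normal(1.76, 0.08, n))
    bmi = np.clip(rng.normal(27.0, 4.3, n), 16.0, 50.0)
    weight = bmi * height**2
    waist = (
        np.where(female, 84.0, 97.0)
        + 1.6 * (bmi - 27.0)
        + rng.normal(0.0, 6.0, n)
    )
    sbp = rng.normal(138.0, 18.0, n) + 0.5 * (age_baseline - 55.0)
    dbp = rng.normal(82.0, 10.0, n)
    hypertension_history = rng.random(n) < 0.12
    antihypertensive_meds = rng.random(n) < 0.10
    t2d_history = rng.random(n) < 0.035
    glucose_lowering_meds = rng.random(n) < 0.02
    hba1c = rng.normal(5.4, 0.45, n) + 1.6 * t2d_history
    fasting_glucose = rng.normal(95.0, 12.0, n) + 40.0 * t2d_history
    cvd = rng.random(n) < 0.036
    stroke = rng.random(n) < 0.03
    longstanding_illness = rng.random(n) < 0.10
    poor_self_rated_health = rng.random(n) < 0.12
    prs = rng.normal(0.0, 1.0, n)

    return pd.DataFrame(
        {
            "participant_id": ids,
            "sex": sex,
            "age_baseline": age_baseline,
            "age_scan": age_scan,
            "education_degree": education_degree,
            "race": race,
            "deprivation": deprivation,
            "smoking": smoking,
            "physical_activity": activity,
            "height_m": height,
            "weight_kg": weight,
            "waist_cm": waist,
            "sbp": sbp,
            "dbp": dbp,
            "hypertension_history": hypertension_history,
            "antihypertensive_meds": antihypertensive_meds,
            "t2d_history": t2d_history,
            "glucose_lowering_meds": glucose_lowering_meds,
            "hba1c_pct": hba1c,
            "fasting_glucose_mgdl": fasting_glucose,
            "cvd": cvd,
            "stroke": stroke,
            "longstanding_illness": longstanding_illness,
            "poor_self_rated_health": poor_self_rated_health,
            "prs": prs,
        }
    ).set_index("participant_id")


def _draw_diet(
    config: SimulationConfig,
    reference: dii_mod.DIIReference,
    covar: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-assessment intakes plus the latent diet tendency factor."""
    n = config.n_participants
    params = reference.table
    p = len(params)

    dep_z = (covar["deprivation"].to_numpy() - (-1.9)) / 2.7
    tendency = (
        0.18 * dep_z
        + 0.35 * (covar["smoking"] == "current").to_numpy()
        + 0.22 * (~covar["education_degree"].to_numpy(dtype=bool))
        + 0.12 * (covar["sex"] == "female").to_numpy()
        + 0.15 * (covar["physical_activity"] == "low").to_numpy()
        - 0.12 * (covar["physical_activity"] == "high").to_numpy()
        + 0.92 * rng.normal(0.0, 1.0, n)
    )
    tendency = (tendency - tendency.mean()) / tendency.std()

    # participant-stable log-intake deviations, aligned with weight signs
    lam = config.diet_inflammatory_loading * np.sign(params["weight"].to_numpy())
    stable = lam * tendency[:, None] + np.sqrt(1 - lam**2) * rng.normal(0, 1, (n, p))

    k = rng.choice(
        np.arange(1, len(config.assessment_count_probs) + 1),
        size=n,
        p=config.assessment_count_probs,
    )
    has_baseline = rng.random(n) < config.frac_baseline_assessment
    k = np.where(~has_baseline & (k > 4), 4, k)  # only 4 online cycles exist

    # participant-level usual energy, negatively tied to the tendency factor
    base_energy = np.where(covar["sex"] == "female", 1950.0, 2300.0)
    usual_energy = base_energy - 160.0 * tendency + rng.normal(0.0, 380.0, n)
    usual_energy = np.clip(usual_energy, 750.0, 4100.0)

    rows_pid, rows_cycle = [], []
    for i in range(n):
        cycles = (["baseline"] if has_baseline[i] else []) + list(
            rng.choice(ASSESSMENT_CYCLES[1:], size=int(k[i]) - has_baseline[i], replace=False)
        )
        rows_pid.extend([covar.index[i]] * len(cycles))
        rows_cycle.extend(cycles)
    n_rows = len(rows_pid)
    row_of = covar.index.get_indexer(rows_pid)

    log_mu = np.log(params["global_mean"].to_numpy())
    log_x = (
        log_mu
        + config.nutrient_sd_log * stable[row_of]
        + config.within_person_sd_log * rng.normal(0.0, 1.0, (n_rows, p))
    )
    intakes = np.exp(log_x)

    energy = usual_energy[row_of] + rng.normal(0.0, 230.0, n_rows)
    # a small fraction of assessments report implausible energy
    wild = rng.random(n_rows) < 0.012
    energy = np.where(wild, energy * rng.choice([0.28, 1.9], size=n_rows), energy)

    diet = pd.DataFrame(intakes, columns=params["name"].tolist())
    diet.insert(0, dii_mod.ID_COL, rows_pid)
    diet.insert(1, dii_mod.CYCLE_COL, rows_cycle)
    diet.insert(2, dii_mod.ENERGY_COL, energy)
    return diet, tendency


def _true_dii(
    diet: pd.DataFrame, covar: pd.DataFrame, reference: dii_mod.DIIReference
) -> pd.Series:
    """The DII that drives biology: plausibility-filtered, multi-assessment
    average, with an all-assessment fallback for fully excluded participants."""
    kept, report = dii_mod.filter_plausible_assessments(diet, covar["sex"])
    scores = dii_mod.compute_dii(
        dii_mod.average_intakes(kept).drop(columns=[dii_mod.ENERGY_COL]), reference
    )
    true_dii = scores["dii"].reindex(covar.index)
    excluded = report.loc[report["excluded"], dii_mod.ID_COL]
    if len(excluded):
        fallback = dii_mod.compute_dii(
            dii_mod.average_intakes(
                diet[diet[dii_mod.ID_COL].isin(excluded)]
            ).drop(columns=[dii_mod.ENERGY_COL]),
            reference,
        )
        true_dii.loc[fallback.index] = fallback["dii"]
    return true_dii


def _draw_blood(
    config: SimulationConfig,
    true_dii: pd.Series,
    covar: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Blood markers whose shared latent factor tracks the true DII."""
    n = len(covar)
    coupling = config.infla_per_dii if config.prop_mediated_true > 0 else 0.0
    dii_c = true_dii.to_numpy() - np.nanmean(true_dii.to_numpy())
    bmi = covar["weight_kg"].to_numpy() / covar["height_m"].to_numpy() ** 2
    latent = (
        coupling * dii_c
        + 0.06 * (bmi - 27.0) / 4.3
        + 0.10 * (covar["smoking"] == "current").to_numpy()
        + rng.normal(0.0, 1.0, n)
    )
    crp = np.exp(-0.35 + 0.30 * latent + 0.85 * rng.normal(0, 1, n))
    wbc = np.clip(6.9 + 0.8 * latent + 1.5 * rng.normal(0, 1, n), 1.5, None)
    platelets = np.clip(252 + 18 * latent + 56 * rng.normal(0, 1, n), 50, None)
    neutrophils = np.clip(4.2 + 0.55 * latent + 1.0 * rng.normal(0, 1, n), 0.5, None)
    lymphocytes = np.clip(1.95 - 0.12 * latent + 0.5 * rng.normal(0, 1, n), 0.4, None)
    blood = pd.DataFrame(
        {
            "crp": crp,
            "wbc": wbc,
            "platelets": platelets,
            "neutrophils": neutrophils,
            "lymphocytes": lymphocytes,
        },
        index=covar.index,
    )
    return blood, latent


def _adjusted_infla_dii_slope(
    infla: np.ndarray, true_dii: np.ndarray, covar: pd.DataFrame
) -> float:
    """Realised covariate-adjusted OLS slope of INFLA-score on DII."""
    bmi = covar["weight_kg"].to_numpy() / covar["height_m"].to_numpy() ** 2
    design = np.column_stack(
        [
            np.ones(len(covar)),
            true_dii,
            covar["age_baseline"].to_numpy(),
            (covar["sex"] == "male").to_numpy(dtype=float),
            (covar["race"] == "other").to_numpy(dtype=float),
            covar["education_degree"].to_numpy(dtype=float),
            covar["deprivation"].to_numpy(),
            bmi,
            (covar["smoking"] == "former").to_numpy(dtype=float),
            (covar["smoking"] == "current").to_numpy(dtype=float),
            (covar["physical_activity"] == "moderate").to_numpy(dtype=float),
            (covar["physical_activity"] == "high").to_numpy(dtype=float),
            covar["cvd"].to_numpy(dtype=float),
            covar["t2d_history"].to_numpy(dtype=float),
            covar["prs"].to_numpy(),
        ]
    )
    mask = np.isfinite(infla) & np.isfinite(true_dii)
    coef = np.linalg.lstsq(design[mask], infla[mask], rcond=None)[0]
    return float(coef[1])


def generate_cohort(
    config: SimulationConfig, reference: dii_mod.DIIReference
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Dietary assessments, blood markers, covariates and ground truth.

    The BAG equation splits ``beta_dii_bag`` into a direct part
    ``(1 - p) * beta`` and an inflammation-mediated part whose INFLA-score
    slope is calibrated against the realised covariate-adjusted
    INFLA-on-DII slope of this very sample, so ACME/total equals
    ``prop_mediated_true`` by construction.
    """
    if len(reference.table) == 0:
        raise SchemaError("reference table is empty")
    covar = _draw_covariates(config, _rng(config.seed, 1))
    diet, tendency = _draw_diet(config, reference, covar, _rng(config.seed, 2))
    true_dii = _true_dii(diet, covar, reference)
    blood, latent = _draw_blood(config, true_dii, covar, _rng(config.seed, 3))

    infla_scores = infla_mod.compute_infla(blood)["infla"].to_numpy()
    dii_arr = true_dii.to_numpy()
    dii_c = dii_arr - np.nanmean(dii_arr)

    beta = config.beta_dii_bag
    p_med = config.prop_mediated_true
    a_real = _adjusted_infla_dii_slope(infla_scores, dii_arr, covar)
    if p_med > 0 and beta != 0 and abs(a_real) > 0.02:
        b_infla = p_med * beta / a_real
        beta_direct = (1 - p_med) * beta
    else:
        b_infla = 0.0
        beta_direct = beta

    rng_out = _rng(config.seed, 4)
    bmi = covar["weight_kg"].to_numpy() / covar["height_m"].to_numpy() ** 2
    dep_z = (covar["deprivation"].to_numpy() - (-1.9)) / 2.7
    bag = (
        beta_direct * dii_c
        + b_infla * (infla_scores - np.nanmean(infla_scores))
        + 0.80 * (covar["smoking"] == "current").to_numpy()
        + 0.25 * (covar["smoking"] == "former").to_numpy()
        + 0.04 * (bmi - 27.0)
        + 0.06 * dep_z
        + 1.00 * covar["t2d_history"].to_numpy(dtype=float)
        + 0.40 * (
            (covar["sbp"].to_numpy() >= 140)
            | (covar["dbp"].to_numpy() >= 90)
            | covar["hypertension_history"].to_numpy(dtype=bool)
            | covar["antihypertensive_meds"].to_numpy(dtype=bool)
        ).astype(float)
        + 0.60 * covar["cvd"].to_numpy(dtype=float)
        + 0.15 * covar["prs"].to_numpy()
        + 0.20 * (covar["sex"] == "male").to_numpy(dtype=float)
        + rng_out.normal(0.0, config.bag_noise_sd, len(covar))
    )

    groups = dii_mod.assign_dii_group(np.nan_to_num(dii_arr))
    if config.group_bag_effects:
        shift = np.array([config.group_bag_effects.get(int(g), 0.0) for g in groups])
        bag = bag + shift
    if config.age_group_bag_effects:
        stratum = np.where(covar["age_baseline"].to_numpy() >= 60, "older", "middle")
        shift = np.array(
            [
                config.age_group_bag_effects.get(s, {}).get(int(g), 0.0)
                for s, g in zip(stratum, groups)
            ]
        )
        bag = bag + shift

    truth = SyntheticTruth(
        participants=pd.DataFrame(
            {
                "true_dii": dii_arr,
                "true_infla_latent": latent,
                "true_bag": bag,
                "true_brain_age": covar["age_scan"].to_numpy() + bag,
            },
            index=covar.index,
        ),
        params={
            "beta_dii_bag": beta,
            "prop_mediated_true": p_med,
            "beta_direct": beta_direct,
            "b_infla": b_infla,
            "a_infla_dii_realized": a_real,
            "bag_noise_sd": config.bag_noise_sd,
            "seed": config.seed,
        },
    )

    covar_out = covar.copy()
    rng_gen = _rng(config.seed, 6)
    covar_out["rs429358"] = _draw_genotypes(rng_gen, len(covar), "C", "T", 0.15)
    covar_out["rs7412"] = _draw_genotypes(rng_gen, len(covar), "C", "T", 0.92)

    _inject_missingness(config, covar_out, blood, _rng(config.seed, 7))
    return diet, blood, covar_out, truth


def _draw_genotypes(rng, n, allele_a, allele_b, freq_a):
    alleles = np.where(rng.random((n, 2)) < freq_a, allele_a, allele_b)
    return ["".join(sorted(pair)) for pair in alleles]


def _inject_missingness(config, covar, blood, rng) -> None:
    for column, rate in (config.missingness_rates or {}).items():
        for table in (covar, blood):
            if column in table.columns:
                mask = rng.random(len(table)) < rate
                table.loc[mask, column] = np.nan


def generate_idps(truth: SyntheticTruth, config: SimulationConfig) -> IDPMatrix:
    """Noisy linear readouts of true brain age, grouped by modality.

    Column j of modality m is ``loading_j * true_brain_age + N(0,
    idp_noise_sd)`` with loadings drawn from ``idp_age_loading_range``.
    The realised loadings are stored on ``truth.idp_loadings`` for
    parameter-recovery tests. Optional missingness (key ``"idps"`` in
    ``missingness_rates``) knocks out entries at random.
    """
    rng = _rng(config.seed, 5)
    t = truth.participants["true_brain_age"].to_numpy()
    columns, modality_of = [], {}
    for modality, count in config.idp_modality_counts.items():
        for j in range(count):
            name = f"{modality}_{j + 1:04d}"
            columns.append(name)
            modality_of[name] = modality
    lo, hi = config.idp_age_loading_range
    loadings = rng.uniform(lo, hi, len(columns))
    noise = rng.normal(0.0, config.idp_noise_sd, (len(t), len(columns)))
    data = pd.DataFrame(
        t[:, None] * loadings[None, :] + noise,
        index=truth.participants.index,
        columns=columns,
    )
    rate = (config.missingness_rates or {}).get("idps", 0.0)
    if rate:
        mask = rng.random(data.shape) < rate
        data = data.mask(mask)
    truth.idp_loadings = pd.Series(loadings, index=columns)
    return IDPMatrix(data=data, modalities=modality_of)


def simulate(
    config: SimulationConfig, reference: dii_mod.DIIReference | None = None,
    n_reference_params: int = 31,
) -> SimulatedCohort:
    """Generate a complete synthetic cohort (reference, tables, IDPs, truth)."""
    if reference is None:
        reference = generate_reference(n_reference_params, config.seed)
    diet, blood, covar, truth = generate_cohort(config, reference)
    idps = generate_idps(truth, config)
    return SimulatedCohort(
        reference=reference,
        dietary_assessments=diet,
        blood_markers=blood,
        covariates=covar,
        idps=idps,
        truth=truth,
    )
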