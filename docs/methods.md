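# Methods

`inflammage` implements a complete analysis chain linking the inflammatory
potential of diet to machine-learning-derived brain aging, together with a
synthetic cohort generator that makes every stage testable against known
ground truth. This note records the models, the parameter choices, and the
design decisions that were genuinely open.

## Dietary Inflammatory Index (DII)

Each dietary parameter *i* carries a signed inflammatory effect weight
*w<sub>i</sub>* (negative = anti-inflammatory) and a global reference mean
μ<sub>i</sub> and SD σ<sub>i</sub> of daily intake. For a participant's mean
intake *x<sub>i</sub>*:

    z_i = (x_i − μ_i) / σ_i
    c_i = 2·Φ(z_i) − 1            (centered percentile in (−1, 1))
    DII = Σ_i c_i · w_i

The percentile conversion uses the standard-normal CDF, which is the
construction of the original index; a diet at the global mean of every
parameter therefore scores exactly 0, and |DII| ≤ Σ|w<sub>i</sub>| always.
DII is monotone in each intake in the direction of its weight, and invariant
to affine reparameterisation of a parameter's units.

Quality control before scoring follows standard cohort practice:

* **Energy plausibility.** An assessment is kept iff energy is within
  [600, 3500] kcal/day for females or [800, 4200] for males, bounds
  *inclusive* (the exclusion rule is strict inequality). A participant is
  excluded only when no assessment survives. The same bounds are applied at
  the assessment level and (implicitly) the participant level; no second
  bound set is defined.
* **Averaging.** Nutrients are averaged over all kept assessments and one
  DII is computed per participant. Per-assessment DII is computed only for
  the baseline-only mediation variant and the stability diagnostic.
* **Subset scoring.** Scoring on a subset of the reference parameters
  (e.g. 31 of 45) is permitted behind an explicit `allow_missing` flag with
  a logged list of absent parameters; no re-weighting is applied. The
  packaged reference table is synthetic (weights drawn with mixed signs);
  published weights are a drop-in CSV with columns
  `name,weight,global_mean,global_sd`.

Groups use the conventional cut points: 1: DII < −2; 2: −2 ≤ DII < 0;
3: 0 ≤ DII < 2; 4: DII ≥ 2. Stability between an earlier and a later set of
assessments is reported as Pearson r plus Bland–Altman mean difference and
95% limits of agreement (mean ± 1.96 SD of paired differences).

## INFLA-score

A composite of low-grade systemic inflammation from four markers: CRP
(mg/L), white-cell count, platelet count (both 10⁹/L) and the
neutrophil-to-lymphocyte ratio. Marker values in the 7th–10th decile of the
reference distribution score +1..+4; the 1st–4th decile scores −4..−1. The
middle deciles score 0 — implied, not stated, by the published −16..+16
range, and recorded here as an inference. Decile rank for value *v* is the
smallest *k* with *v* ≤ cutpoint<sub>k</sub> (else 10), so ties fall into
the lower decile; this is a deterministic tie rule chosen in the absence of
a stated one. The reference distribution defaults to the analysis sample
itself; external cut points can be supplied as JSON for reproducibility
across subsets or to score against cohort-wide deciles. The composite depends on marker values only
through ranks, hence is invariant to monotone transformations of a column.

## Brain age and brain age gap

1. **Complete cases.** Rows with any missing IDP are excluded and counted.
2. **Healthy reference subset.** Participants free of stroke, type-2
   diabetes, long-standing illness/disability/frailty and fair-or-poor
   self-rated health; a missing flag excludes conservatively. Published
   inclusion flowcharts often report overlapping per-condition exclusion
   counts that do not sum to the final subset size; the boolean-AND rule is
   the implementable definition, and flowchart counts are handled as
   validated cascade fixtures rather than re-derived.
3. **Split.** The healthy subset is split 4:1 (train:validation) with a
   seeded shuffle; the training size is round-half-away-from-zero of 0.8 n
   (4,355 → 3,484/871).
4. **Standardisation.** Every IDP is z-scored with means/SDs computed from
   training rows only and applied to all rows; zero-SD columns are dropped
   with a warning, never imputed. Deleting any non-training row changes
   nothing (no leakage).
5. **Model zoo.** L1-penalised linear regression, gradient-boosted trees
   and RBF support-vector regression, each with or without recursive
   feature elimination (3×2 grid). Hyperparameters are tuned by a bounded,
   seeded search with training-internal cross-validation (LassoCV over a
   four-point alpha grid; small randomized searches for the tree and SVR
   models). RFECV ranks features with an L1 linear model for all three
   predictors because SVR-rbf exposes no importances. The cell with the
   lowest validation MAE (computed on raw predictions, before bias
   correction) is selected. Large runs default to the single-cell `lasso`
   grid — the cell such zoos typically select on standardised IDP data.
6. **Bias correction.** Brain-age models overpredict in the young and
   underpredict in the old. Regressing raw training predictions on
   chronological age gives slope α and intercept β; corrected brain age is
   `(raw − β)/α`. The shorthand *original − β/α* often quoted for this
   correction is ambiguous about operator order; the
   subtraction-then-division reading is adopted because it is the only one
   that yields slope-1/intercept-0 calibration of corrected-on-chronological
   age on the training set, which is asserted to 1e−8 in the tests. The
   correction also exactly undoes any linear shrinkage of the predictor, so
   estimated BAG is an (approximately) unbiased readout of true BAG.
7. **BAG** = corrected brain age − chronological age at scan; positive
   means an older-looking brain.

Model persistence is portable JSON for linear models (coefficients plus
standardisation constants). Tree/SVR models are not persisted — they are
cheap to refit from the run configuration, and the package deliberately
avoids opaque binary artifacts.

## Association analyses

Ordinary least squares via statsmodels with two adjustment sets:

* **basic**: age at baseline, sex, race, education, Townsend deprivation;
* **multivariable**: basic + energy intake, BMI, smoking, physical
  activity, CVD, T2D, hypertension, PRS.

Age at baseline is used in the adjustment set (scan age is switchable);
categorical covariates use reference-cell dummies (references: DII group 1,
female, white, never-smoker, low activity, low tertile, non-carrier).
Confidence intervals use t quantiles (df = n − p); at cohort n the normal
and t are indistinguishable. No multiple-testing adjustment is applied.
Least-squares means evaluate the fitted group model on every used row with
the group dummies forced to each level and average the predictions
(equivalently, prediction at the averaged design row), with delta-method
SEs. Stratified analyses drop the modifier and any covariate it nests
(continuous age for age strata, continuous PRS for PRS tertiles, BMI for
BMI categories); the interaction p-value is a joint Wald test of all
exposure×modifier product terms in a pooled model. Rank-deficient designs
are refused with the collinear columns named. Sensitivity re-runs
(assessment-count subsets, covariate swaps such as APOE4 for PRS) are row
filters and term swaps on the same code path, not separate implementations.

## Mediation

Linear mediation without exposure–mediator interaction, estimated from
first principles on one jointly listwise-deleted row set:
a = exposure coefficient in the mediator model; b and c′ = mediator and
exposure coefficients in the outcome model. ACME = a·b, ADE = c′,
total = c′ + a·b (equal, exactly and algebraically, to the exposure
coefficient of the outcome-only model on the same rows), proportion
mediated = ACME/total, reported signed. Inference is a nonparametric
case-resampling bootstrap (default 1,000 replicates, percentile 2.5/97.5
CIs). The quasi-Bayesian machinery of the standard mediation package
coincides with this estimand for linear models without interaction; the
bootstrap keeps ACME + ADE = total exact on every replicate. Replicates
with |total| below 1e−10 are excluded from the proportion's CI (counted;
more than 10% flags the CI unstable). The proportion-mediated ratio is
intrinsically unstable when the total effect is near zero — visible in the
wide CIs this estimator produces at n ≈ 4,400 — which is a property of the
estimand, not of the implementation. For that reason the bootstrap reports
the proportion's point estimate as the median of the replicate proportions
(the convention of the standard mediation machinery), while ACME, ADE and
the total effect keep their full-sample estimates; the analytic plug-in
ratio remains available from `mediation_point_estimate`.

For the reverse-causality-guarded variant, DII can be computed from the
baseline-cycle assessment only (`baseline_only_dii`); participants without
a plausible baseline assessment are excluded and counted. In linear models,
exposure measurement error attenuates a and c′ by the same reliability
factor, so the proportion mediated is essentially invariant to which DII
variant is used; the recovery experiments use the averaged-assessment DII
(the exposure the generator wires to the outcome) to avoid the extra ratio
noise.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes; it
does not attempt to replicate any real cohort's marginals precisely.

* **Covariates.** Sex (53.6% female), baseline age uniform on [40, 70],
  scan lag N(8.7, 1.5²) years, plus education, race, deprivation, smoking,
  activity, anthropometrics, blood pressures, disease flags, PRS ~ N(0,1)
  and the two APOE SNPs with realistic allele frequencies (rs429358-C 0.15,
  rs7412-C 0.92). Marginals are documented in `synth._draw_covariates`.
* **Diet.** A latent "diet inflammatory tendency" factor (loaded on
  deprivation, smoking, low education/activity, sex) drives log-normal
  nutrient intakes around the reference means, with loadings aligned with
  the sign of each parameter's weight (loading 0.28, between-person log-SD
  0.30, within-person log-SD 0.25). These values were chosen so the
  realised DII spans roughly −6..+5 with an SD near 1.9, the spread
  reported for large cohorts, and so repeated assessments correlate
  imperfectly. 1–5 assessments per participant (29/27/22/14/8%), with a
  baseline-cycle assessment for 21% by default; 1.2% of assessments get
  wild energy values to exercise the plausibility filter.
* **Inflammation.** A latent inflammation factor depends linearly on the
  realised DII (0.045 SD units per DII unit, yielding an adjusted
  INFLA-on-DII slope near 0.18) plus adiposity and smoking; the four
  markers are noisy readouts of it. When `prop_mediated_true = 0` the
  coupling is switched off entirely, so markers are independent of diet
  given covariates.
* **Outcome.** True BAG = direct DII effect + b·(INFLA-score − mean) +
  covariate effects + optional group/stratum shifts + N(0, 4²) years. The
  4-year residual SD is a typical brain-age residual scale and makes
  recovery of a 0.07 y effect at n ≈ 20,000 borderline-significant — the
  regime of interest. Because the INFLA-score is a rank composite, its
  regression slope on DII cannot be fixed a priori; the generator therefore
  calibrates b against the realised covariate-adjusted INFLA-on-DII slope
  of the very sample it drew, making ACME/total equal `prop_mediated_true`
  by construction. All BAG covariate effects are linear in covariates that
  belong to the multivariable adjustment set, so the adjusted estimator is
  unbiased for the configured effects.
* **IDPs.** Column j is loading<sub>j</sub>·(true brain age) + N(0, 5²),
  loadings uniform on [0.4, 1.2], with modality labels apportioned from the
  published six-modality proportions (largest remainder, exact sums; the
  full-scale schema reproduces 165/1/14/675/210/14 = 1,079). With 200
  columns the combined age signal is strong, so the bias-corrected model
  recovers true BAG with slope ≈ 1; per-column noise keeps each individual
  IDP realistically weak. Missingness is off by default and injected only
  to test complete-case behaviour.
* **Truth separation.** True DII, latent inflammation, true BAG/brain age
  and realised effect parameters live in a separate truth object that no
  estimator receives; `true brain age = age at scan + true BAG` exactly.

What passing recovery tests do **not** show: the generator's linear,
Gaussian, correctly-specified world cannot detect misspecification biases
(non-linear dose-response, residual confounding, selection effects,
assay drift) that real cohort data would carry.

## Problem sizes and numerical choices

Recovery experiments use 20 seeded cohorts of n = 20,000 with 200 IDPs for
association targets, and 20 cohorts of n = 4,439 (every participant with a
baseline assessment) with 1,000 bootstrap replicates for mediation — sizes
chosen to match the studied regime while keeping a full run on a single
CPU in minutes. One simulated-and-analysed cohort of n = 20,000 takes
roughly 8 s. Degenerate inputs are refused loudly (zero-SD reference,
zero-variance labels, α ≈ 0 bias slopes, rank-deficient designs,
sub-minimum split sizes); ties in decile/tertile assignment always fall
into the lower bin. All randomness flows from explicit integer seeds
through named `numpy` generator streams; there is no global random state.

## Known limitations

* The packaged DII reference weights are synthetic stand-ins; scientific
  use requires the published weight table.
* The INFLA decile reference and PRS tertiles are sample-internal by
  default; cross-cohort comparisons need exported cut points.
* Mediation assumes sequential ignorability and no exposure–mediator
  interaction; no sensitivity analysis for either is provided.
* The phase-ambiguous APOE diplotype (both SNPs heterozygous) is flagged,
  not imputed; downstream analyses treat it as missing.
* Figures are not emitted; all outputs are tidy tables ready for external
  plotting.
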