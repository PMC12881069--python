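"""Brain-age workflow: split, standardisation, model selection, bias correction."""

import numpy as np
import pandas as pd
import pytest

from inflammage import brainage, synth
from inflammage.errors import InsufficientDataError, ValidationError


class TestHealthySubset:
    def _cohort(self, flags):
        n = len(next(iter(flags.values())))
        base = {c: [False] * n for c in brainage.HEALTHY_EXCLUSION_FLAGS}
        base.update(flags)
        return pd.DataFrame(base, index=[f"P{i}" for i in range(n)])

    def test_all_flags_false_included(self):
        ids, counts = brainage.select_healthy_subset(self._cohort({"stroke": [False, False]}))
        assert len(ids) == 2 and counts["n_healthy"] == 2

    def test_single_condition_excludes(self):
        ids, _ = brainage.select_healthy_subset(
            self._cohort({"t2d_history": [True, False]})
        )
        assert list(ids) == ["P1"]

    def test_missing_flag_excludes_conservatively(self):
        ids, _ = brainage.select_healthy_subset(
            self._cohort({"stroke": [None, False]})
        )
        assert list(ids) == ["P1"]

    def test_mask_oracle_on_synthetic_cohort(self, small_sim):
        cohort = small_sim.covariates
        ids, counts = brainage.select_healthy_subset(cohort)
        flags = cohort[list(brainage.HEALTHY_EXCLUSION_FLAGS)].astype(bool)
        expected = (~flags.any(axis=1)).sum()
        assert counts["n_healthy"] == expected == len(ids)


class TestSplit:
    def test_printed_cohort_sizes(self):
        ids = [f"P{i}" for i in range(4355)]
        train, val = brainage.split_train_validation(ids, seed=1)
        assert (len(train), len(val)) == (3484, 871)

    def test_minimum_split(self):
        train, val = brainage.split_train_validation(list("abcde"), seed=0)
        assert (len(train), len(val)) == (4, 1)

    def test_disjoint_exhaustive_deterministic(self):
        ids = [f"P{i}" for i in range(103)]
        t1, v1 = brainage.split_train_validation(ids, seed=9)
        t2, v2 = brainage.split_train_validation(ids[::-1], seed=9)  # order-free
        assert set(t1) | set(v1) == set(ids) and not set(t1) & set(v1)
        assert list(t1) == list(t2) and list(v1) == list(v2)

    def test_too_few_ids(self):
        with pytest.raises(InsufficientDataError):
            brainage.split_train_validation(list("abcd"), seed=0)


class TestStandardize:
    def _idps(self, n=60, p=5, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(3.0, 2.0, (n, p)),
            index=[f"P{i}" for i in range(n)],
            columns=[f"idp{j}" for j in range(p)],
        )

    def test_training_columns_unit_scale(self):
        idps = self._idps()
        train = idps.index[:40]
        std, constants, dropped = brainage.standardize_idps(idps, train)
        assert np.abs(std.loc[train].mean()).max() < 1e-10
        assert np.abs(std.loc[train].std(ddof=0) - 1).max() < 1e-10
        assert dropped == []

    def test_two_pass_oracle_on_heldout_rows(self):
        idps = self._idps()
        train = idps.index[:40]
        std, constants, _ = brainage.standardize_idps(idps, train)
        mean = idps.loc[train].to_numpy().mean(axis=0)
        sd = idps.loc[train].to_numpy().std(axis=0)
        expected = (idps.to_numpy() - mean) / sd
        assert np.allclose(std.to_numpy(), expected, atol=1e-12)

    def test_row_at_training_mean_maps_to_zero(self):
        idps = self._idps()
        train = idps.index[:40]
        idps.loc["Pnew"] = idps.loc[train].mean()
        std, *_ = brainage.standardize_idps(idps, train)
        assert np.abs(std.loc["Pnew"]).max() < 1e-10

    def test_no_leakage_from_test_rows(self):
        idps = self._idps()
        train = idps.index[:40]
        _, constants_full, _ = brainage.standardize_idps(idps, train)
        _, constants_dropped, _ = brainage.standardize_idps(idps.iloc[:-5], train)
        pd.testing.assert_frame_equal(constants_full, constants_dropped)

    def test_zero_sd_column_dropped(self):
        idps = self._idps()
        idps["flat"] = 1.0
        std, constants, dropped = brainage.standardize_idps(idps, idps.index[:40])
        assert dropped == ["flat"] and "flat" not in std.columns


class TestBiasCorrection:
    def test_perfect_model(self):
        ages = np.linspace(45, 80, 50)
        alpha, beta = brainage.fit_bias_correction(ages, ages)
        assert alpha == pytest.approx(1.0, abs=1e-12)
        assert beta == pytest.approx(0.0, abs=1e-9)

    def test_exact_linear_case_and_inversion(self):
        ages = np.linspace(45, 80, 50)
        preds = 0.5 * ages + 30
        alpha, beta = brainage.fit_bias_correction(preds, ages)
        assert (alpha, beta) == (pytest.approx(0.5), pytest.approx(30.0))
        assert brainage.apply_bias_correction(65.0, 0.5, 30.0) == pytest.approx(70.0)
        assert brainage.apply_bias_correction(np.array([70.0]), 1.0, 0.0)[0] == 70.0

    def test_normal_equations_oracle_on_noisy_run(self):
        rng = np.random.default_rng(5)
        ages = rng.uniform(45, 80, 200)
        preds = 0.8 * ages + 10 + rng.normal(0, 3, 200)
        alpha, beta = brainage.fit_bias_correction(preds, ages)
        X = np.column_stack([np.ones_like(ages), ages])
        coef = np.linalg.solve(X.T @ X, X.T @ preds)
        assert alpha == pytest.approx(coef[1], abs=1e-10)
        assert beta == pytest.approx(coef[0], abs=1e-8)

    def test_post_correction_calibration(self):
        # after correction, training regression of corrected on chronological
        # age has slope 1 / intercept 0 — the disambiguation property
        rng = np.random.default_rng(8)
        ages = rng.uniform(45, 80, 400)
        preds = 0.73 * ages + 18 + rng.normal(0, 2.5, 400)
        alpha, beta = brainage.fit_bias_correction(preds, ages)
        corrected = brainage.apply_bias_correction(preds, alpha, beta)
        slope, intercept = np.polyfit(ages, corrected, 1)
        assert slope == pytest.approx(1.0, abs=1e-8)
        assert intercept == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_inputs_refused(self):
        with pytest.raises(ValidationError):
            brainage.fit_bias_correction([1.0, 1.0, 1.0], [50.0, 50.0, 50.0])
        with pytest.raises(ValidationError):
            brainage.apply_bias_correction([60.0], 0.0, 5.0)
        ages = np.linspace(45, 80, 30)
        with pytest.raises(ValidationError):
            brainage.fit_bias_correction(np.zeros(30), ages)


class TestBAG:
    def test_sign_convention(self):
        out = brainage.compute_bag([66.0, 64.0], [64.0, 64.0])
        assert out["bag"].tolist() == [2.0, 0.0]

    def test_positive_age_required(self):
        with pytest.raises(ValidationError):
            brainage.compute_bag([60.0], [-1.0])


class TestTrainAndSelect:
    def _separable(self, n=300, p=15, noise=0.0, seed=3):
        rng = np.random.default_rng(seed)
        ages = rng.uniform(45, 80, n)
        loadings = rng.uniform(0.5, 1.5, p)
        x = ages[:, None] * loadings[None, :] + rng.normal(0, noise, (n, p))
        idx = [f"P{i}" for i in range(n)]
        idps = pd.DataFrame(x, index=idx, columns=[f"idp{j}" for j in range(p)])
        return idps, pd.Series(ages, index=idx)

    def test_noiseless_signal_near_zero_mae(self):
        idps, ages = self._separable(noise=0.0)
        train, val = idps.index[:240], idps.index[240:]
        std, constants, _ = brainage.standardize_idps(idps, train)
        model = brainage.train_and_select(
            std.loc[train], ages.loc[train], std.loc[val], ages.loc[val],
            grid="lasso", seed=1,
        )
        assert model.validation_mae < 0.1

    def test_singleton_grid_returns_that_model(self):
        idps, ages = self._separable(noise=2.0)
        train, val = idps.index[:240], idps.index[240:]
        std, *_ = brainage.standardize_idps(idps, train)
        model = brainage.train_and_select(
            std.loc[train], ages.loc[train], std.loc[val], ages.loc[val],
            grid=[("lasso", "none")], seed=1,
        )
        assert (model.model_name, model.feature_selection) == ("lasso", "none")
        assert model.n_nonzero_coef is not None

    def test_full_grid_selects_minimum_validation_mae(self):
        idps, ages = self._separable(n=220, p=12, noise=3.0)
        train, val = idps.index[:170], idps.index[170:]
        std, *_ = brainage.standardize_idps(idps, train)
        model = brainage.train_and_select(
            std.loc[train], ages.loc[train], std.loc[val], ages.loc[val],
            grid="full", seed=2, n_iter=3,
        )
        table = model.mae_table
        assert len(table) == 6  # 3 predictors x 2 feature-selection modes
        assert model.validation_mae == table["validation_mae"].min()

    def test_degenerate_label_rejected(self):
        idps, ages = self._separable(n=50)
        std, *_ = brainage.standardize_idps(idps, idps.index[:40])
        with pytest.raises(ValidationError):
            brainage.train_and_select(
                std.iloc[:40], np.full(40, 60.0), std.iloc[40:], ages.iloc[40:]
            )


class TestEndToEnd:
    def test_no_leakage_when_test_rows_removed(self):
        config = synth.SimulationConfig(n_participants=350, seed=31, n_idps=15)
        sim = synth.simulate(config, n_reference_params=8)
        idps, cohort = sim.idps.data, sim.covariates
        bag1, model1, info1 = brainage.estimate_brain_age_gap(
            idps, cohort, grid="lasso", seed=31
        )
        healthy, _ = brainage.select_healthy_subset(cohort)
        test_only = [i for i in idps.index if i not in set(healthy)][:5]
        keep = idps.index.difference(test_only)
        bag2, model2, info2 = brainage.estimate_brain_age_gap(
            idps.loc[keep], cohort.loc[keep], grid="lasso", seed=31
        )
        pd.testing.assert_series_equal(model1.means, model2.means)
        assert info1["bias_alpha"] == pytest.approx(info2["bias_alpha"], abs=1e-12)
        common = bag1.index.intersection(bag2.index)
        assert np.allclose(bag1.loc[common, "bag"], bag2.loc[common, "bag"])

    def test_incomplete_idp_rows_counted_and_excluded(self):
        config = synth.SimulationConfig(n_participants=300, seed=33, n_idps=12)
        sim = synth.simulate(config, n_reference_params=8)
        idps = sim.idps.data.copy()
        idps.iloc[5, 3] = np.nan
        idps.iloc[17, 0] = np.nan
        bag, _, info = brainage.estimate_brain_age_gap(
            idps, sim.covariates, grid="lasso", seed=33
        )
        assert info["n_incomplete_idp_excluded"] == 2
        assert idps.index[5] not in bag.index

    def test_bag_recovery_slope(self, analysis_table):
        sim, table = analysis_table
        merged = table.join(sim.truth.participants[["true_bag"]]).dropna(
            subset=["bag", "true_bag"]
        )
        slope = np.polyfit(merged["true_bag"], merged["bag"], 1)[0]
        assert 0.8 <= slope <= 1.1
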