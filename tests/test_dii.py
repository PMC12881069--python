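"""DII scoring: QC filter, averaging, centered-percentile scoring, groups."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from inflammage import dii
from inflammage.errors import (
    InsufficientDataError,
    ScoringError,
    ValidationError,
)


def _phi(z):
    """Standard-normal CDF via the error function (test-side oracle)."""
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def make_reference(weights, means=None, sds=None):
    k = len(weights)
    return dii.DIIReference(
        pd.DataFrame(
            {
                "name": [f"p{i}" for i in range(k)],
                "weight": weights,
                "global_mean": means if means is not None else [10.0] * k,
                "global_sd": sds if sds is not None else [2.0] * k,
            }
        )
    )


class TestPlausibilityFilter:
    def _assessments(self, rows):
        return pd.DataFrame(rows, columns=["participant_id", "cycle", "energy_kcal"])

    def test_sex_specific_bounds_keep_and_exclude(self):
        assessments = self._assessments(
            [
                ("F1", "baseline", 550.0),   # below female lower bound
                ("F1", "online1", 1800.0),   # plausible
                ("M1", "baseline", 4300.0),  # above male upper bound
            ]
        )
        sex = pd.Series({"F1": "female", "M1": "male"})
        kept, report = dii.filter_plausible_assessments(assessments, sex)
        assert len(kept) == 1 and kept.iloc[0]["participant_id"] == "F1"
        rep = report.set_index("participant_id")
        assert rep.loc["F1", "n_kept"] == 1 and not rep.loc["F1", "excluded"]
        assert rep.loc["M1", "n_kept"] == 0 and rep.loc["M1", "excluded"]

    @pytest.mark.parametrize(
        "sex,energy,kept",
        [
            ("female", 600.0, True),    # bounds are inclusive
            ("female", 3500.0, True),
            ("female", 599.9, False),
            ("female", 3500.1, False),
            ("male", 800.0, True),
            ("male", 4200.0, True),
            ("male", 799.9, False),
        ],
    )
    def test_boundary_inclusive(self, sex, energy, kept):
        assessments = self._assessments([("P1", "baseline", energy)])
        out, _ = dii.filter_plausible_assessments(
            assessments, pd.Series({"P1": sex})
        )
        assert (len(out) == 1) is kept

    def test_unknown_sex_names_participant(self):
        assessments = self._assessments([("P9", "baseline", 2000.0)])
        with pytest.raises(ValidationError, match="P9"):
            dii.filter_plausible_assessments(assessments, pd.Series({"P9": "unknown"}))


class TestAveraging:
    def test_mean_over_assessments(self):
        table = pd.DataFrame(
            {
                "participant_id": ["A", "A", "B"],
                "cycle": ["baseline", "online1", "baseline"],
                "energy_kcal": [2000.0, 2200.0, 1500.0],
                "fiber": [10.0, 20.0, 7.0],
            }
        )
        means = dii.average_intakes(table)
        assert means.loc["A", "fiber"] == 15.0
        assert means.loc["A", "energy_kcal"] == 2100.0
        assert means.loc["B", "fiber"] == 7.0  # single assessment: identity

    def test_five_assessment_mean_matches_direct(self):
        values = [12.0, 18.5, 9.75, 14.0, 21.25]
        table = pd.DataFrame(
            {
                "participant_id": ["A"] * 5,
                "cycle": list("abcde"),
                "energy_kcal": [2000.0] * 5,
                "fiber": values,
            }
        )
        assert dii.average_intakes(table).loc["A", "fiber"] == pytest.approx(
            sum(values) / 5, abs=1e-12
        )


class TestComputeDII:
    def test_mean_diet_scores_exactly_zero(self):
        ref = make_reference([0.5, -0.3, 0.2])
        intake = pd.DataFrame(
            [ref.table["global_mean"].to_numpy()], columns=ref.names, index=["A"]
        )
        out = dii.compute_dii(intake, ref)
        assert out.loc["A", "dii"] == 0.0

    def test_three_parameter_hand_computation(self):
        # weights (+0.5, -0.3, +0.2) at z = (1, -1, 0)
        ref = make_reference([0.5, -0.3, 0.2], means=[10, 20, 30], sds=[2, 4, 5])
        intake = pd.DataFrame(
            [[12.0, 16.0, 30.0]], columns=ref.names, index=["A"]
        )
        expected = (2 * _phi(1) - 1) * 0.5 + (2 * _phi(-1) - 1) * (-0.3)
        assert expected == pytest.approx(0.546151593709669, abs=1e-12)
        out = dii.compute_dii(intake, ref)
        assert out.loc["A", "dii"] == pytest.approx(expected, abs=1e-10)

    def test_saturation_limit(self):
        ref = make_reference([-0.663])
        intake = pd.DataFrame([[10.0 + 2.0 * 1000]], columns=ref.names)
        out, contrib = dii.compute_dii(intake, ref, return_contributions=True)
        assert contrib.iloc[0, 0] == pytest.approx(-0.663, abs=1e-9)
        assert abs(out["dii"].iloc[0]) <= ref.abs_weight_sum

    def test_missing_parameter_requires_flag(self):
        ref = make_reference([0.5, -0.3])
        intake = pd.DataFrame([[10.0]], columns=["p0"])
        with pytest.raises(ScoringError):
            dii.compute_dii(intake, ref)
        out = dii.compute_dii(intake, ref, allow_missing=True)
        assert out["n_params_used"].iloc[0] == 1

    def test_invalid_reference_sd_rejected(self):
        with pytest.raises(ValidationError):
            make_reference([0.5], sds=[0.0])


class TestGroups:
    @pytest.mark.parametrize(
        "value,group",
        [(-2.5, 1), (-2.0, 2), (-0.001, 2), (0.0, 3), (1.999, 3), (2.0, 4), (7.0, 4)],
    )
    def test_cut_points(self, value, group):
        assert dii.assign_dii_group(value) == group

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            dii.assign_dii_group(float("nan"))

    @given(st.floats(min_value=-50, max_value=50, allow_nan=False))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_partition(self, value):
        assert dii.assign_dii_group(value) in (1, 2, 3, 4)


class TestStability:
    def test_identical_vectors(self):
        scores = np.array([1.0, -0.5, 2.0, 0.3, -1.2])
        rep = dii.dii_stability(scores, scores)
        assert rep["pearson_r"] == pytest.approx(1.0)
        assert rep["mean_difference"] == 0.0
        assert rep["loa_lower"] == rep["loa_upper"] == 0.0

    def test_anticorrelated(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        rep = dii.dii_stability(a, -a)
        assert rep["pearson_r"] == pytest.approx(-1.0)

    def test_ten_pair_textbook_formulas(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 2, 10)
        b = 0.5 * a + rng.normal(0, 1, 10)
        rep = dii.dii_stability(a, b)
        # direct textbook evaluation
        r = (((a - a.mean()) * (b - b.mean())).sum()
             / np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()))
        d = a - b
        assert rep["pearson_r"] == pytest.approx(r, abs=1e-12)
        assert rep["mean_difference"] == pytest.approx(d.mean(), abs=1e-12)
        assert rep["loa_upper"] == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)

    def test_zero_variance_reported_undefined(self):
        rep = dii.dii_stability([1.0, 1.0, 1.0], [0.5, 1.0, 1.5])
        assert not rep["r_defined"]

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            dii.dii_stability([1.0, 2.0], [1.0, 2.0])


class TestInvariants:
    @given(
        z=st.lists(st.floats(-4, 4), min_size=4, max_size=4),
        bump=st.floats(0.1, 20),
        idx=st.integers(0, 3),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_signed_weight_direction(self, z, bump, idx):
        weights = [0.4, -0.6, 0.25, -0.1]
        ref = make_reference(weights)
        mu = ref.table["global_mean"].to_numpy()
        sd = ref.table["global_sd"].to_numpy()
        x = mu + sd * np.asarray(z)
        x2 = x.copy()
        x2[idx] += bump
        base = dii.compute_dii(pd.DataFrame([x], columns=ref.names), ref)["dii"][0]
        raised = dii.compute_dii(pd.DataFrame([x2], columns=ref.names), ref)["dii"][0]
        if weights[idx] > 0:
            assert raised >= base - 1e-12
        else:
            assert raised <= base + 1e-12

    @given(st.lists(st.floats(-6, 6), min_size=4, max_size=4))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bound_by_abs_weight_sum(self, z):
        ref = make_reference([0.4, -0.6, 0.25, -0.1])
        mu = ref.table["global_mean"].to_numpy()
        sd = ref.table["global_sd"].to_numpy()
        x = mu + sd * np.asarray(z)
        out = dii.compute_dii(pd.DataFrame([x], columns=ref.names), ref)
        assert abs(out["dii"][0]) <= ref.abs_weight_sum + 1e-12

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_affine_reparameterisation_invariance(self, a, b):
        z = np.array([0.7, -1.3, 0.2])
        ref = make_reference([0.5, -0.3, 0.2])
        mu = ref.table["global_mean"].to_numpy()
        sd = ref.table["global_sd"].to_numpy()
        x = mu + sd * z
        base = dii.compute_dii(pd.DataFrame([x], columns=ref.names), ref)["dii"][0]
        ref2 = make_reference([0.5, -0.3, 0.2], means=a * mu + b, sds=a * sd)
        out2 = dii.compute_dii(pd.DataFrame([a * x + b], columns=ref2.names), ref2)
        assert out2["dii"][0] == pytest.approx(base, abs=1e-9)
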