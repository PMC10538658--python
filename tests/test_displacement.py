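import numpy as np
import pandas as pd
import pytest

import circadian_gate as cg
from circadian_gate.displacement import (
    condition_rhythm_pvalues,
    displacement_cohorts,
)
from conftest import make_cpm

T = np.arange(28.0, 49.0, 4.0)


def cosine(phase, amp, base):
    return base + amp * np.cos(2 * np.pi * (T - 24.0 - phase) / 24.0)


class TestAdjustedDelta:
    def test_matching_next_value_gives_zero(self, design):
        ctrl = np.array([10.0, 12.0, 15.0, 13.0, 11.0, 9.0])
        cold = np.roll(ctrl, -1)  # cold(ZTx) has no meaning here except:
        cold = np.concatenate([[0.0], ctrl[:-1]])  # cold(ZTx+4) = control(ZTx)
        cpm = make_cpm(design, ctrl[None, :], cold[None, :])
        adj = cg.compute_adjusted_delta(cpm, design)
        assert np.allclose(adj.loc["g0"], 0.0)

    def test_perfectly_stabilized_gene(self, design):
        # cold trajectory lags the control by one sampling interval
        ctrl = cosine(6.0, 20.0, 50.0)
        cold = cosine(6.0 + 4.0, 20.0, 50.0)
        cpm = make_cpm(design, ctrl[None, :], cold[None, :])
        adj = cg.compute_adjusted_delta(cpm, design)
        assert np.allclose(adj.loc["g0"], 0.0, atol=1e-9)

    def test_constant_offset_gene(self, design):
        ctrl = np.full(6, 30.0)
        cpm = make_cpm(design, ctrl[None, :], (ctrl + 7.0)[None, :])
        adj = cg.compute_adjusted_delta(cpm, design)
        assert np.allclose(adj.loc["g0"], 7.0)

    def test_uses_cold_next_not_control_next(self, design):
        # asymmetric construction: swapping the roles of the conditions
        # changes the adjusted profile
        ctrl = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
        cold = np.array([60.0, 50.0, 40.0, 30.0, 20.0, 10.0])
        cpm = make_cpm(design, ctrl[None, :], cold[None, :])
        adj = cg.compute_adjusted_delta(cpm, design).loc["g0"].to_numpy()
        expected = cold[1:] - ctrl[:-1]
        np.testing.assert_allclose(adj, expected)
        swapped = ctrl[1:] - cold[:-1]
        assert not np.allclose(adj, swapped)

    def test_columns_are_all_but_last_timepoint(self, design, small_dataset):
        cpm = cg.compute_cpm(small_dataset.counts)
        adj = cg.compute_adjusted_delta(cpm, design)
        assert list(adj.columns) == [28, 32, 36, 40, 44]


class TestDisplacementRatio:
    def _ratio(self, design, ctrl, cold):
        cpm = make_cpm(design, ctrl[None, :], cold[None, :])
        delta = cg.compute_delta_cpm(cpm, design)
        adj = cg.compute_adjusted_delta(cpm, design)
        return cg.displacement_ratio(delta, adj).loc["g0"]

    def test_perfect_stabilization_ratio_zero(self, design):
        ctrl = cosine(6.0, 20.0, 50.0)
        cold = cosine(10.0, 20.0, 50.0)  # = control shifted by 4 h
        row = self._ratio(design, ctrl, cold)
        assert row["ratio"] == pytest.approx(0.0, abs=1e-12)
        assert row["ratio_class"] == "<0.5"

    def test_constant_offset_ratio_one(self, design):
        ctrl = np.full(6, 30.0)
        row = self._ratio(design, ctrl, ctrl + 12.0)
        assert row["ratio"] == pytest.approx(1.0)
        assert row["ratio_class"] == ">=1"

    def test_quarter_ratio_from_direct_arithmetic(self, design):
        delta = pd.DataFrame([[4.0] * 6], index=["g0"], columns=[28, 32, 36, 40, 44, 48])
        adj = pd.DataFrame([[1.0] * 5], index=["g0"], columns=[28, 32, 36, 40, 44])
        row = cg.displacement_ratio(delta, adj).loc["g0"]
        assert row["mean_delta"] == 4.0 and row["mean_adj_delta"] == 1.0
        assert row["ratio"] == pytest.approx(0.25)
        assert row["ratio_class"] == "<0.5"

    def test_zero_mean_delta_undefined(self, design):
        ctrl = np.full(6, 30.0)
        row = self._ratio(design, ctrl, ctrl)
        assert np.isnan(row["ratio"]) and pd.isna(row["ratio_class"])

    def test_class_boundaries(self):
        delta = pd.DataFrame(
            [[2.0] * 6] * 3, index=list("abc"), columns=[28, 32, 36, 40, 44, 48]
        )
        adj = pd.DataFrame(
            [[2.0] * 5, [1.5] * 5, [0.9] * 5],
            index=list("abc"),
            columns=[28, 32, 36, 40, 44],
        )
        out = cg.displacement_ratio(delta, adj)
        assert list(out["ratio_class"]) == [">=1", "<1", "<0.5"]


class TestCohorts:
    def _calls(self, genes, gated_direction=None):
        calls = pd.DataFrame(
            {
                "rhythm_p": 1.0,
                "direction": pd.NA,
                "gated": False,
            },
            index=pd.Index(genes, name="gene_id"),
        )
        if gated_direction:
            for g, d in gated_direction.items():
                calls.loc[g, ["direction", "gated"]] = [d, True]
        return calls

    def test_gated_induction_excluded_from_delta_cohort(self):
        ratios = pd.DataFrame(
            {"ratio": [0.4, 0.6], "ratio_class": ["<0.5", "<1"]},
            index=pd.Index(["up", "disp"], name="gene_id"),
        )
        delta_p = pd.Series([0.01, 0.01], index=["up", "disp"])
        calls = self._calls(["up", "disp"], {"up": "induction", "disp": "displacement"})
        cohorts = displacement_cohorts(ratios, delta_p, None, calls)
        genes = set(cohorts["rhythmic_delta"]["genes"])
        assert genes == {"disp"}
        cohorts_all = displacement_cohorts(ratios, delta_p, None, calls, exclude="all-gated")
        assert set(cohorts_all["rhythmic_delta"]["genes"]) == set()

    def test_empty_inputs_give_empty_cohorts(self):
        ratios = pd.DataFrame(columns=["ratio", "ratio_class"])
        cohorts = displacement_cohorts(
            ratios, pd.Series(dtype=float), None, self._calls([])
        )
        assert cohorts["rhythmic_delta"]["n"] == 0
        assert cohorts["rhythmic_delta"]["n_lt1"] == 0

    def test_both_condition_cohort_requires_both_rhythms(self):
        ratios = pd.DataFrame(
            {"ratio": [0.4, 0.4], "ratio_class": ["<0.5", "<0.5"]},
            index=pd.Index(["both", "one"], name="gene_id"),
        )
        cond_p = pd.DataFrame(
            {cg.CONTROL: [0.01, 0.01], cg.COLD: [0.01, 0.5]},
            index=["both", "one"],
        )
        cohorts = displacement_cohorts(
            ratios, pd.Series(1.0, index=["both", "one"]), cond_p, self._calls(["both", "one"])
        )
        assert set(cohorts["rhythmic_both_conditions"]["genes"]) == {"both"}

    def test_stabilized_triad_members_all_below_one(self, design):
        # clock-gene use case: a stabilized triad's members all have ratio < 1
        rng = np.random.default_rng(0)
        rows_ctrl, rows_cold, genes = [], [], []
        for sub in "ABD":
            ctrl = cosine(8.0, 30.0, 60.0)
            cold = cosine(11.0, 30.0, 60.0)  # held for the 3 h treatment
            rows_ctrl.append(ctrl + rng.normal(0, 0.5, 6))
            rows_cold.append(cold + rng.normal(0, 0.5, 6))
            genes.append(f"TraesCS1{sub}02G000100")
        cpm = make_cpm(design, np.array(rows_ctrl), np.array(rows_cold), genes=genes)
        ana = cg.DisplacementAnalysis().fit(cpm, design)
        assert (ana.results_["ratio"] < 1).all()


class TestConditionRhythms:
    def test_rhythmic_gene_detected_in_both_conditions(self, design):
        prof = cosine(4.0, 25.0, 60.0)
        rng = np.random.default_rng(1)
        cpm = make_cpm(design, prof[None, :], prof[None, :])
        cpm += rng.normal(0, 0.5, cpm.shape)
        pvals = condition_rhythm_pvalues(cpm, design)
        assert (pvals.loc["g0"] < 0.05).all()

    def test_replicate_and_mean_modes_agree_on_strong_signal(self, design):
        prof = cosine(16.0, 25.0, 60.0)
        cpm = make_cpm(design, prof[None, :], prof[None, :])
        p_rep = condition_rhythm_pvalues(cpm, design, use_replicates=True)
        p_mean = condition_rhythm_pvalues(cpm, design, use_replicates=False)
        assert (p_rep.loc["g0"] < 0.05).all() and (p_mean.loc["g0"] < 0.05).all()
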