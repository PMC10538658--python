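import numpy as np
import pandas as pd
import pytest

import circadian_gate as cg
from circadian_gate.simulate import GATED_CLASSES, cpm_noise_sd


def truth(**kw):
    base = dict(gene_id="g", response_class="non_responsive", baseline_mean=100.0)
    base.update(kw)
    return cg.GeneTruth(**base)


class TestGeneTruthInvariants:
    def test_etmr_required_iff_gated(self):
        with pytest.raises(ValueError, match="true_etmr"):
            truth(response_class="gated_induction", response_magnitude=10.0)
        with pytest.raises(ValueError, match="true_etmr"):
            truth(response_class="rhythmic_only", true_etmr=4.0)

    def test_magnitude_zero_iff_non_responsive(self):
        with pytest.raises(ValueError, match="magnitude"):
            truth(response_class="non_responsive", response_magnitude=5.0)
        with pytest.raises(ValueError, match="magnitude"):
            truth(response_class="uniform_response", response_magnitude=0.0)

    def test_amplitude_bounds(self):
        with pytest.raises(ValueError, match="amplitude"):
            truth(rhythm_amplitude=1.0)


class TestExpectedTrajectory:
    def test_rhythmic_only_cosine_peak(self, design):
        t = truth(
            response_class="rhythmic_only", rhythm_amplitude=0.5, rhythm_phase=0.0
        )
        exp = cg.expected_trajectory(t, design)
        for sid in design.sample_ids(zt=48):
            assert exp[sid] == pytest.approx(150.0)  # cos(0) = 1, zero response

    def test_non_responsive_flat(self, design):
        exp = cg.expected_trajectory(truth(), design)
        assert np.allclose(exp, 100.0)

    def test_gated_induction_peaks_at_etmr(self, design):
        t = truth(
            response_class="gated_induction",
            true_etmr=16.0,
            response_magnitude=50.0,
            gate_width=8.0,
        )
        exp = cg.expected_trajectory(t, design)
        delta = {
            zt: exp[design.sample_ids(cg.COLD, zt)[0]]
            - exp[design.sample_ids(cg.CONTROL, zt)[0]]
            for zt in design.timepoints
        }
        assert delta[40] == pytest.approx(50.0)  # ZT40 = phase 16 = gate centre
        assert delta[28] == pytest.approx(0.0)  # 12 h away, outside the gate
        assert max(delta.values()) == delta[40]

    def test_reduction_mirrors_induction(self, design):
        kw = dict(true_etmr=16.0, response_magnitude=30.0, gate_width=8.0)
        up = cg.expected_trajectory(truth(response_class="gated_induction", **kw), design)
        down = cg.expected_trajectory(truth(response_class="gated_reduction", **kw), design)
        cold = design.sample_ids(cg.COLD, 40)[0]
        ctrl = design.sample_ids(cg.CONTROL, 40)[0]
        assert up[cold] - up[ctrl] == pytest.approx(-(down[cold] - down[ctrl]))

    def test_stabilized_holds_treatment_start_value(self, design):
        t = truth(
            response_class="stabilized",
            rhythm_amplitude=0.5,
            rhythm_phase=6.0,
            response_magnitude=20.0,
        )
        exp = cg.expected_trajectory(t, design)
        for zt in design.timepoints:
            cold = exp[design.sample_ids(cg.COLD, zt)[0]]
            held = 100.0 * (1 + 0.5 * np.cos(2 * np.pi * (zt - 3 - 24 - 6.0) / 24.0))
            assert cold == pytest.approx(held)


class TestSampleCounts:
    def test_same_seed_bit_identical(self, design):
        t = [truth(gene_id=f"g{i}") for i in range(5)]
        exp = pd.DataFrame([cg.expected_trajectory(x, design) for x in t])
        cfg = cg.SimulationConfig(seed=7)
        a = cg.sample_counts(exp, cfg)
        b = cg.sample_counts(exp, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_expectation_gives_zero_counts(self, design):
        exp = pd.DataFrame(
            np.zeros((3, 36)), columns=design.samples.index, index=list("abc")
        )
        counts = cg.sample_counts(exp, cg.SimulationConfig(seed=1))
        assert (counts.to_numpy() == 0).all()

    def test_negative_expectation_rejected(self, design):
        exp = pd.DataFrame(
            np.full((1, 36), -1.0), columns=design.samples.index, index=["a"]
        )
        with pytest.raises(ValueError, match=">= 0"):
            cg.sample_counts(exp, cg.SimulationConfig(seed=1))

    def test_poisson_limit_mean(self, design):
        # dispersion -> 0: mean count equals expected CPM at 1e6 library size
        exp = pd.DataFrame(
            np.full((400, 36), 100.0), columns=design.samples.index,
            index=[f"g{i}" for i in range(400)],
        )
        cfg = cg.SimulationConfig(seed=3, dispersion=0.0, library_size=1e6)
        counts = cg.sample_counts(exp, cfg)
        assert counts.to_numpy().mean() == pytest.approx(100.0, rel=0.01)

    def test_nb_moments(self, design):
        # empirical mean/variance match mu and mu + phi mu^2 at 1,000 draws
        mu, phi = 200.0, 0.1
        exp = pd.DataFrame(
            np.full((1000, 36), mu), columns=design.samples.index,
            index=[f"g{i}" for i in range(1000)],
        )
        cfg = cg.SimulationConfig(seed=5, dispersion=phi, library_size=1e6)
        vals = cg.sample_counts(exp, cfg).to_numpy().ravel()
        assert vals.mean() == pytest.approx(mu, rel=0.02)
        assert vals.var() == pytest.approx(mu + phi * mu**2, rel=0.05)


class TestGenerateDataset:
    def test_deterministic(self):
        cfg = cg.SimulationConfig(seed=9, n_genes={"rhythmic_only": 30})
        a, b = cg.generate_dataset(cfg), cg.generate_dataset(cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert a.truth == b.truth

    def test_empty_config_valid_design(self):
        ds = cg.generate_dataset(cg.SimulationConfig(seed=1, n_genes={}))
        assert len(ds.counts) == 0
        assert ds.counts.shape[1] == 36

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicate"):
            cg.SimulationConfig(seed=1, n_replicates=0)

    def test_round_robin_etmr_assignment(self):
        cfg = cg.SimulationConfig(
            seed=2, n_genes={"gated_induction": 600}, triad_fraction=0.0
        )
        ds = cg.generate_dataset(cfg)
        etmrs = pd.Series([t.true_etmr for t in ds.truth])
        assert (etmrs.value_counts() == 100).all()
        assert set(etmrs) == {2.0, 6.0, 10.0, 14.0, 18.0, 22.0}

    def test_full_triad_fraction_gives_complete_triads(self):
        cfg = cg.SimulationConfig(
            seed=4, n_genes={"rhythmic_only": 30}, triad_fraction=1.0
        )
        ds = cg.generate_dataset(cfg)
        assert all(t.triad_id is not None for t in ds.truth)
        assert len(ds.triads) == 10
        members = set(ds.triads[["gene_A", "gene_B", "gene_D"]].to_numpy().ravel())
        assert members == {t.gene_id for t in ds.truth}

    def test_truth_counts_alignment(self, small_dataset):
        assert [t.gene_id for t in small_dataset.truth] == list(small_dataset.counts.index)

    def test_subgenome_bias_applies_only_in_window(self):
        base = cg.SimulationConfig(
            seed=6, n_genes={"gated_induction": 60}, triad_fraction=1.0,
            normalize_cpm_total=False,
        )
        biased = cg.SimulationConfig(
            seed=6, n_genes={"gated_induction": 60}, triad_fraction=1.0,
            subgenome_bias={"D": 2.0}, bias_etmr_window=(12.0, 24.0),
            normalize_cpm_total=False,
        )
        t0 = {t.gene_id: t for t in cg.generate_dataset(base).truth}
        t1 = {t.gene_id: t for t in cg.generate_dataset(biased).truth}
        for gid, t in t1.items():
            factor = t.response_magnitude / t0[gid].response_magnitude
            if t.subgenome == "D" and t.true_etmr >= 12.0:
                assert factor == pytest.approx(2.0)
            else:
                assert factor == pytest.approx(1.0)

    def test_write_round_trips_counts(self, tmp_path, small_dataset):
        small_dataset.write(tmp_path)
        counts, _ = cg.load_counts(tmp_path / "counts.tsv", tmp_path / "design.tsv")
        pd.testing.assert_frame_equal(counts, small_dataset.counts, check_dtype=False)

    def test_delta_argmax_near_etmr_for_strong_genes(self, small_dataset):
        # recoverability precondition: strong gated genes peak at the
        # sampled timepoint nearest their true ETMR
        ds = small_dataset
        cpm = cg.compute_cpm(ds.counts)
        delta = cg.compute_delta_cpm(cpm, ds.design)
        cfg = cg.SimulationConfig(seed=7)
        checked = 0
        for t in ds.truth:
            if t.response_class != "gated_induction":
                continue
            if t.response_magnitude < 5 * cpm_noise_sd(t, cfg):
                continue
            peak_zt = delta.loc[t.gene_id].idxmax()
            expected_zt = cg.data.nearest_timepoint(t.true_etmr)
            dist = cg.data.circular_distance_h(peak_zt % 24, expected_zt % 24)
            assert dist <= 4.0
            checked += 1
        assert checked > 5
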