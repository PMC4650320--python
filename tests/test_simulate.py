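import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from airseq.cpg import cg_count
from airseq.simulate import (
    PLANTED_CONSENSI,
    SimulationConfig,
    make_family_table,
    make_pwm_library,
    make_truth,
    simulate_counts,
    simulate_promoters,
)


class TestDeterminism:
    def test_identical_seed_bit_identical(self):
        cfg = SimulationConfig(n_genes=300, seed=42)
        cm1, t1 = simulate_counts(cfg)
        cm2, t2 = simulate_counts(cfg)
        assert cm1.counts.equals(cm2.counts)
        assert t1.lps_up.equals(t2.lps_up)
        s1, a1 = simulate_promoters(t1, cfg)
        s2, a2 = simulate_promoters(t2, cfg)
        assert s1 == s2 and a1 == a2

    def test_different_seed_differs(self):
        cm1, _ = simulate_counts(SimulationConfig(n_genes=300, seed=1))
        cm2, _ = simulate_counts(SimulationConfig(n_genes=300, seed=2))
        assert not cm1.counts.equals(cm2.counts)


class TestLabels:
    def test_air_implies_lps_up(self):
        for seed in range(3):
            truth = make_truth(SimulationConfig(n_genes=500, seed=seed))
            assert not (truth.air & ~truth.lps_up).to_numpy().any()

    def test_eosinophil_il10_effects_disabled_by_default(self):
        truth = make_truth(SimulationConfig(n_genes=500, seed=0))
        assert not truth.air["eosinophil"].any()
        assert not truth.il10_up["eosinophil"].any()
        assert truth.il10_responsive["eosinophil"] is False

    def test_module_fractions_over_one_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            SimulationConfig(lps_common_frac=0.5, lps_specific_frac=0.3,
                             il10_up_frac=0.2, celltype_frac=0.2)


class TestCountModel:
    def test_null_model_groups_indistinguishable(self):
        """With all effects at 1 no treatment should shift any gene."""
        cfg = SimulationConfig(
            n_genes=400, cell_types=("macrophage",), n_replicates=4,
            lps_effect=1.0, air_suppression=1.0, il10_effect=1.0,
            celltype_effect=1.0, library_size_factors=tuple([1.0] * 16),
            seed=5,
        )
        cm, _ = simulate_counts(cfg)
        g = cm.groups()
        a = cm.counts[g[("macrophage", "ctrl")]].to_numpy()
        b = cm.counts[g[("macrophage", "LPS")]].to_numpy()
        log_a, log_b = np.log1p(a), np.log1p(b)
        p = sps.ttest_ind(log_a, log_b, axis=1).pvalue
        assert (p > 0.01).mean() >= 0.98

    def test_poisson_limit_variance_equals_mean(self):
        cfg = SimulationConfig(
            n_genes=200, cell_types=("macrophage",), treatments=("ctrl",),
            n_replicates=40, dispersion=0.0, lps_effect=1.0,
            air_suppression=1.0, il10_effect=1.0, celltype_effect=1.0,
            library_size_factors=tuple([1.0] * 40), seed=3,
        )
        cm, _ = simulate_counts(cfg)
        x = cm.counts.to_numpy()
        ratio = x.var(axis=1, ddof=1) / x.mean(axis=1)
        assert abs(np.median(ratio) - 1.0) < 0.15

    def test_planted_lps_effect_recovered(self):
        cfg = SimulationConfig(
            n_genes=1000, lps_effect=6.0, n_replicates=3, seed=7,
            library_size_factors=tuple([1.0] * 60),
        )
        cm, truth = simulate_counts(cfg)
        g = cm.groups()
        lps_genes = truth.lps_up["macrophage"].to_numpy()
        m_lps = cm.counts[g[("macrophage", "LPS")]].to_numpy()[lps_genes].mean()
        m_ctrl = cm.counts[g[("macrophage", "ctrl")]].to_numpy()[lps_genes].mean()
        assert abs(m_lps / m_ctrl - 6.0) < 0.2 * 6.0

    def test_effect_monotonicity(self):
        """Mean planted log2FC estimate strictly increases with lps_effect."""
        estimates = []
        for effect in (2.0, 4.0, 8.0):
            cfg = SimulationConfig(
                n_genes=600, lps_effect=effect, seed=11,
                library_size_factors=tuple([1.0] * 40),
            )
            cm, truth = simulate_counts(cfg)
            g = cm.groups()
            lps_genes = truth.lps_up["macrophage"].to_numpy()
            m1 = cm.counts[g[("macrophage", "LPS")]].to_numpy()[lps_genes].mean(axis=1)
            m0 = cm.counts[g[("macrophage", "ctrl")]].to_numpy()[lps_genes].mean(axis=1)
            estimates.append(np.mean(np.log2((m1 + 1) / (m0 + 1))))
        assert estimates[0] < estimates[1] < estimates[2]

    def test_air_suppression_applied_only_in_responsive_cells(self):
        cfg = SimulationConfig(n_genes=800, seed=2,
                               library_size_factors=tuple([1.0] * 40))
        cm, truth = simulate_counts(cfg)
        g = cm.groups()
        air = truth.air["macrophage"].to_numpy()
        m_lps = cm.counts[g[("macrophage", "LPS")]].to_numpy()[air].mean()
        m_both = cm.counts[g[("macrophage", "IL10_LPS")]].to_numpy()[air].mean()
        assert m_lps / m_both > 2.0  # planted 4-fold decline


class TestPromoters:
    def test_rich_vs_poor_cg_separation(self):
        cfg = SimulationConfig(n_genes=800, seed=9, plant_motif_in="none")
        truth = make_truth(cfg)
        seqs, annots = simulate_promoters(truth, cfg)
        from airseq.cpg import extract_window

        counts = {}
        for a in annots:
            w = extract_window(a, seqs)
            counts[a.gene] = cg_count(w)
        rich = [counts[g] for g in truth.cpg_class.index[truth.cpg_class == "rich"]]
        poor = [counts[g] for g in truth.cpg_class.index[truth.cpg_class == "poor"]]
        assert len(rich) >= 200 and len(poor) >= 200
        assert np.mean(rich) >= 2.0 * np.mean(poor)
        p = sps.mannwhitneyu(rich[:200], poor[:200]).pvalue
        assert p < 0.01

    def test_planted_consensus_present_in_every_target_window(self):
        cfg = SimulationConfig(n_genes=400, seed=4)
        truth = make_truth(cfg)
        seqs, annots = simulate_promoters(truth, cfg)
        from airseq.cpg import extract_window

        consensus = PLANTED_CONSENSI[cfg.motif_id]
        targets = set(truth.planted_motif.index[truth.planted_motif == cfg.motif_id])
        assert targets
        for a in annots:
            if a.gene in targets:
                w = extract_window(a, seqs)
                assert consensus in w.sequence


class TestPwmLibrary:
    def test_planted_plus_decoys(self):
        pwms, planted = make_pwm_library(SimulationConfig(n_decoy_pwms=3, seed=0))
        assert len(pwms) == len(PLANTED_CONSENSI) + 3
        assert planted == set(PLANTED_CONSENSI)

    def test_planted_consensus_and_sharpness(self):
        pwms, planted = make_pwm_library(SimulationConfig(seed=0))
        for pwm in pwms:
            assert np.allclose(pwm.matrix.sum(axis=1), 1.0)
            if pwm.id in planted:
                assert pwm.consensus == PLANTED_CONSENSI[pwm.id]
                assert pwm.information_content() > 1.0


class TestFamilyTable:
    def test_labels_bounded_and_concentrated(self):
        cfg = SimulationConfig(n_genes=1500, seed=6)
        truth = make_truth(cfg)
        fam = truth.family
        assert fam["family"].nunique() <= 20
        lps_anywhere = set(truth.lps_up.index[truth.lps_up.any(axis=1)])
        frac_lps = fam["gene"].isin(lps_anywhere).mean()
        assert frac_lps > 0.5  # cytokines concentrate among LPS responders

    def test_empty_truth_gives_empty_table(self):
        empty = pd.DataFrame(index=[], columns=list("ABC"), dtype=bool)
        out = make_family_table(empty, SimulationConfig())
        assert out.empty
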