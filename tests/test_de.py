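import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from airseq import de as D
from airseq.simulate import simulate_two_group
from airseq.stats import bh_qvalues

from conftest import make_count_matrix


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = make_count_matrix([[5, 5], [9, 9], [2, 2]],
                               treatments=["ctrl", "LPS"])
        sf = D.size_factors(cm)
        assert np.allclose(sf.to_numpy(), 1.0)

    def test_doubled_column(self):
        """B = 2A over 3 all-positive genes -> (1/sqrt(2), sqrt(2))."""
        cm = make_count_matrix([[1, 2], [2, 4], [3, 6]],
                               treatments=["ctrl", "LPS"])
        sf = D.size_factors(cm).to_numpy()
        assert np.allclose(sf, [1 / math.sqrt(2), math.sqrt(2)])
        assert abs(np.exp(np.mean(np.log(sf))) - 1.0) < 1e-9

    def test_single_sample(self):
        cm = make_count_matrix([[3], [4]])
        assert np.allclose(D.size_factors(cm).to_numpy(), [1.0])

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        values = rng.poisson(40, size=(30, 4))
        cm = make_count_matrix(values, treatments=["ctrl"] * 2 + ["LPS"] * 2)
        perm = rng.permutation(30)
        cm_perm = make_count_matrix(values[perm],
                                    treatments=["ctrl"] * 2 + ["LPS"] * 2,
                                    genes=[f"g{i}" for i in perm])
        assert np.allclose(D.size_factors(cm).to_numpy(),
                           D.size_factors(cm_perm).to_numpy())

    def test_global_scaling_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.poisson(40, size=(30, 4)) + 1
        cm = make_count_matrix(values, treatments=["ctrl"] * 2 + ["LPS"] * 2)
        cm_scaled = make_count_matrix(values * 3,
                                      treatments=["ctrl"] * 2 + ["LPS"] * 2)
        assert np.allclose(D.size_factors(cm).to_numpy(),
                           D.size_factors(cm_scaled).to_numpy())

    def test_fallback_when_no_all_positive_row(self):
        cm = make_count_matrix([[0, 5], [5, 0], [4, 4]],
                               treatments=["ctrl", "LPS"])
        sf = D.size_factors(cm)
        assert (sf > 0).all()


class TestDispersion:
    def test_constant_counts_give_zero_raw(self):
        cm = make_count_matrix([[7, 7, 7, 7]] * 5, treatments=["ctrl"] * 4)
        sf = D.size_factors(cm)
        disp = D.estimate_dispersion(cm, sf)
        assert np.allclose(disp.raw.to_numpy(), 0.0)

    def test_poisson_data_has_small_shrunk_alpha(self):
        cm, _ = simulate_two_group(n_genes=2000, n_per_group=6, mu=100,
                                   alpha=0.0, seed=0)
        sf = D.size_factors(cm)
        disp = D.estimate_dispersion(cm, sf)
        assert disp.shrunk.median() <= 0.05

    def test_moment_recovery_of_planted_alpha(self):
        cm, _ = simulate_two_group(n_genes=2000, n_per_group=8, mu=100,
                                   alpha=0.2, seed=1)
        sf = D.size_factors(cm)
        disp = D.estimate_dispersion(cm, sf)
        assert 0.1 <= disp.raw.median() <= 0.3

    def test_all_singleton_groups_error(self):
        cm = make_count_matrix([[5, 6], [7, 8]], treatments=["ctrl", "LPS"])
        sf = D.size_factors(cm)
        with pytest.raises(ValueError, match="replicates"):
            D.estimate_dispersion(cm, sf)


class TestContrast:
    @staticmethod
    def _de(cm, ga, gb, **kw):
        sf = D.size_factors(cm)
        disp = D.estimate_dispersion(cm, sf)
        return D.test_contrast(cm, sf, disp, ga, gb, **kw)

    def test_swap_negates_log2fc_and_keeps_p(self, two_group_cm):
        g = two_group_cm.groups()
        ga, gb = g[("macrophage", "ctrl")], g[("macrophage", "LPS")]
        fwd = self._de(two_group_cm, ga, gb)
        rev = self._de(two_group_cm, gb, ga)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["pvalue"], rev["pvalue"])

    def test_all_zero_gene_flagged_untested(self):
        values = np.full((5, 6), 20)
        values[2] = 0
        cm = make_count_matrix(values, treatments=["ctrl"] * 3 + ["LPS"] * 3)
        res = self._de(cm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        row = res.iloc[2]
        assert not row["tested"]
        assert row["pvalue"] == 1.0 and row["log2fc"] == 0.0

    def test_disjoint_group_requirement(self, two_group_cm):
        g = two_group_cm.groups()
        ga = g[("macrophage", "ctrl")]
        with pytest.raises(ValueError):
            self._de(two_group_cm, ga, ga)

    def test_power_at_planted_fourfold(self):
        cm, is_de = simulate_two_group(n_genes=3000, n_per_group=3, mu=100,
                                       alpha=0.1, effect=4.0, frac_de=0.1,
                                       seed=0)
        g = cm.groups()
        res = self._de(cm, g[("macrophage", "ctrl")], g[("macrophage", "LPS")])
        hit = ((res["qvalue"] < 0.1) & (res["log2fc"] > 0)).to_numpy()
        assert hit[is_de].mean() >= 0.9

    def test_wald_agrees_with_exact_conditional_within_decade(self):
        """Wald p on small counts vs exhaustive conditional enumeration."""
        rng = np.random.default_rng(7)
        values = rng.poisson(4.0, size=(20, 6)) + 1  # small, never all-zero
        cm = make_count_matrix(values, treatments=["ctrl"] * 3 + ["LPS"] * 3)
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = D.DispersionEstimate(
            raw=pd.Series(0.0, index=cm.counts.index),
            shrunk=pd.Series(1e-6, index=cm.counts.index),  # forces Wald path
            trend=(0.0, 0.0),
            base_mean=pd.Series(values.mean(axis=1), index=cm.counts.index),
        )
        res = D.test_contrast(cm, sf, disp, ["s0", "s1", "s2"],
                              ["s3", "s4", "s5"])
        for i in range(20):
            ka = int(values[i, :3].sum())
            kb = int(values[i, 3:].sum())
            tot = ka + kb
            # exact conditional two-sided p by enumerating the binomial pmf
            pmf = sps.binom.pmf(np.arange(tot + 1), tot, 0.5)
            exact = pmf[pmf <= pmf[kb] * (1 + 1e-9)].sum()
            wald = res["pvalue"].iloc[i]
            assert 0.1 <= wald / exact <= 10.0

    def test_exact_path_used_for_tiny_counts_with_zero_alpha(self):
        values = np.array([[0, 0, 0, 3, 4, 5]])
        cm = make_count_matrix(values, treatments=["ctrl"] * 3 + ["LPS"] * 3)
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = D.DispersionEstimate(
            raw=pd.Series(0.0, index=cm.counts.index),
            shrunk=pd.Series(0.0, index=cm.counts.index),
            trend=(0.0, 0.0),
            base_mean=pd.Series(2.0, index=cm.counts.index),
        )
        res = D.test_contrast(cm, sf, disp, ["s0", "s1", "s2"],
                              ["s3", "s4", "s5"])
        expected = sps.binomtest(12, 12, 0.5, alternative="two-sided").pvalue
        assert np.isclose(res["pvalue"].iloc[0], expected)


class TestBH:
    def test_step_up_by_hand(self):
        q = bh_qvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        q = bh_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()


class TestRunAllContrasts:
    def test_long_format_and_scaling_leaves_log2fc_unchanged(self, default_sim):
        cm, _ = default_sim
        de = D.run_all_contrasts(cm, {"LPS_vs_ctrl": ("ctrl", "LPS")})
        assert set(de["contrast"]) == {"LPS_vs_ctrl"}
        assert set(de["cell_type"]) == {s.cell_type for s in cm.samples}
        from airseq.model import CountMatrix
        scaled = CountMatrix((cm.counts * 2).astype(np.int64), cm.samples)
        assert np.allclose(D.size_factors(cm), D.size_factors(scaled))
        de2 = D.run_all_contrasts(scaled, {"LPS_vs_ctrl": ("ctrl", "LPS")})
        # identical up to the pseudocount's shrinking effect on small means
        assert np.allclose(de["log2fc"], de2["log2fc"], atol=0.1)
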