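import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from airseq import classify as C
from airseq.model import AnalysisParams

PARAMS = AnalysisParams()


def de_frame(rows):
    """rows: (gene, cell_type, log2fc, qvalue) for one contrast."""
    return pd.DataFrame(
        [{"gene": g, "cell_type": ct, "contrast": "LPS_vs_ctrl",
          "log2fc": fc, "qvalue": q} for g, ct, fc, q in rows]
    )


class TestCallRegulation:
    def test_relaxation_marks_subthreshold_cell_type(self):
        de = de_frame([
            ("gA", "macrophage", np.log2(4.0), 0.01),
            ("gA", "neutrophil", np.log2(1.6), 0.30),
        ])
        out = C.call_regulation(de, PARAMS).set_index("cell_type")
        assert out.loc["macrophage", "call"] == "up"
        assert out.loc["macrophage", "basis"] == "significant"
        assert out.loc["neutrophil", "call"] == "up"
        assert out.loc["neutrophil", "basis"] == "relaxed"

    def test_fold_change_boundary_is_strict(self):
        de = de_frame([
            ("gA", "macrophage", np.log2(4.0), 0.01),
            ("gA", "neutrophil", np.log2(1.5), 0.30),
        ])
        out = C.call_regulation(de, PARAMS).set_index("cell_type")
        assert out.loc["neutrophil", "call"] == "unchanged"

    def test_no_significant_anchor_means_no_relaxation(self):
        de = de_frame([
            ("gA", "macrophage", np.log2(3.0), 0.50),
            ("gA", "neutrophil", np.log2(3.0), 0.50),
        ])
        out = C.call_regulation(de, PARAMS)
        assert (out["call"] == "unchanged").all()

    def test_direction_must_match_for_relaxation(self):
        de = de_frame([
            ("gA", "macrophage", np.log2(4.0), 0.01),   # significant up
            ("gA", "neutrophil", -np.log2(2.0), 0.30),  # 2-fold *down*
        ])
        out = C.call_regulation(de, PARAMS).set_index("cell_type")
        assert out.loc["neutrophil", "call"] == "unchanged"

    def test_own_cell_type_cannot_anchor_itself(self):
        de = de_frame([("gA", "macrophage", np.log2(4.0), 0.3)])
        out = C.call_regulation(de, PARAMS)
        assert (out["call"] == "unchanged").all()


class TestClassifyAir:
    @staticmethod
    def _means(rows):
        return pd.DataFrame(
            [{"gene": g, "cell_type": ct, "treatment": tr, "mean": m}
             for g, ct, tr, m in rows]
        )

    def test_suppressed_gene_is_air(self):
        means = self._means([
            ("gA", "macrophage", "LPS", 100.0),
            ("gA", "macrophage", "IL10_LPS", 40.0),
        ])
        part = C.classify_air({"macrophage": {"gA"}}, means, PARAMS)
        assert part.air["macrophage"] == {"gA"}

    def test_exact_twofold_is_inclusive(self):
        means = self._means([
            ("gA", "macrophage", "LPS", 100.0),
            ("gA", "macrophage", "IL10_LPS", 50.0),
        ])
        params = PARAMS.with_overrides(pseudocount=0.0)
        part = C.classify_air({"macrophage": {"gA"}}, means, params)
        assert part.air["macrophage"] == {"gA"}

    def test_gene_not_in_lps_up_absent_from_both(self):
        means = self._means([
            ("gA", "macrophage", "LPS", 100.0),
            ("gA", "macrophage", "IL10_LPS", 10.0),
        ])
        part = C.classify_air({"macrophage": set()}, means, PARAMS)
        assert part.air["macrophage"] == set()
        assert part.not_air["macrophage"] == set()

    def test_nonresponsive_cell_type_excluded(self):
        means = self._means([
            ("gA", "eosinophil", "LPS", 100.0),
            ("gA", "eosinophil", "IL10_LPS", 10.0),
        ])
        part = C.classify_air({"eosinophil": {"gA"}}, means, PARAMS,
                              responsive={"eosinophil": False})
        assert "eosinophil" not in part.air

    def test_partition_invariant_union_and_disjoint(self):
        means = self._means(
            [("g%d" % i, "macrophage", "LPS", 100.0) for i in range(10)]
            + [("g%d" % i, "macrophage", "IL10_LPS", 100.0 - 9 * i)
               for i in range(10)]
        )
        lps_up = {"macrophage": {f"g{i}" for i in range(10)}}
        part = C.classify_air(lps_up, means, PARAMS)
        assert part.air["macrophage"] | part.not_air["macrophage"] == lps_up["macrophage"]
        assert not part.air["macrophage"] & part.not_air["macrophage"]


class TestVennPartition:
    def test_enumerated_example(self):
        part = C.venn_partition({"A": {1, 2, 3}, "B": {2, 3, 4}, "C": {3}})
        assert part.categories["unique-A"] == {1}
        assert part.categories["unique-B"] == {4}
        assert part.categories["unique-C"] == set()
        assert part.categories["exactly-2"] == {2}
        assert part.categories["all-3"] == {3}

    def test_identical_sets_all_in_top_category(self):
        part = C.venn_partition({"A": {1, 2}, "B": {1, 2}, "C": {1, 2}})
        assert part.categories["all-3"] == {1, 2}
        assert part.union_size == 2

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            C.venn_partition({"A": {1}})

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(
        st.sets(st.integers(min_value=0, max_value=30)),
        min_size=2, max_size=5,
    ))
    def test_matches_membership_pattern_oracle(self, raw_sets):
        sets = {f"S{i}": s for i, s in enumerate(raw_sets)}
        part = C.venn_partition(sets)
        union = set().union(*sets.values())
        # brute-force oracle: classify every element by membership count
        oracle: dict[str, set] = {k: set() for k in part.categories}
        for x in union:
            count = sum(x in s for s in sets.values())
            if count == len(sets):
                oracle[f"all-{len(sets)}"].add(x)
            elif count == 1:
                name = next(n for n, s in sets.items() if x in s)
                oracle[f"unique-{name}"].add(x)
            else:
                oracle[f"exactly-{count}"].add(x)
        assert part.categories == oracle
        assert part.union_size == len(union)


class TestCelltypeSpecificAir:
    def _partition(self, air):
        not_air = {ct: set() for ct in air}
        return C.AIRPartition(air=air, not_air=not_air)

    def test_single_cell_type_gene_retained(self):
        part = self._partition({"macrophage": {"gA"}, "neutrophil": set()})
        out = C.celltype_specific_air(part)
        assert out["macrophage"] == {"gA"}

    def test_shared_gene_removed_from_both(self):
        part = self._partition({"macrophage": {"gA", "gB"},
                                "neutrophil": {"gA"}})
        out = C.celltype_specific_air(part)
        assert out["macrophage"] == {"gB"}
        assert out["neutrophil"] == set()

    @settings(derandomize=True, max_examples=50)
    @given(st.dictionaries(
        st.sampled_from(["macrophage", "neutrophil", "sDC", "mast"]),
        st.sets(st.integers(min_value=0, max_value=20)),
        min_size=2, max_size=4,
    ))
    def test_outputs_pairwise_disjoint(self, air):
        out = C.celltype_specific_air(self._partition(air))
        names = list(out)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                assert not out[names[i]] & out[names[j]]


class TestMarkRelaxedTargets:
    def _de(self):
        return pd.DataFrame([
            {"gene": "gA", "cell_type": "macrophage",
             "contrast": "IL10_vs_ctrl", "log2fc": np.log2(1.5)},
            {"gene": "gB", "cell_type": "macrophage",
             "contrast": "IL10_vs_ctrl", "log2fc": np.log2(1.49)},
        ])

    def test_boundary_inclusive(self):
        out = C.mark_relaxed_targets(self._de(), ["gA", "gB"], "IL10_vs_ctrl")
        assert out.loc["gA", "macrophage"] is True
        assert out.loc["gB", "macrophage"] is False

    def test_missing_gene_recorded_as_missing(self):
        out = C.mark_relaxed_targets(self._de(), ["gZ"], "IL10_vs_ctrl")
        assert pd.isna(out.loc["gZ", "macrophage"])
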