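"""Gene-set construction: regulation calls, AIR partition, set algebra.

The published analysis works on per-cell-type gene sets derived from DE
results: significant up/down calls (q < 0.1), a cross-cell-type relaxation
(a gene significant in one cell type counts as regulated in another when
its fold-change exceeds 1.5), the AIR / not-AIR split of LPS-induced genes
(AIR = declining at least 2-fold when IL-10 precedes LPS), exclusive Venn
partitions, and cell-type-specific AIR sets with the "any 2 cell types"
genes removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AnalysisParams


@dataclass
class AIRPartition:
    """Per cell type: the AIR / not-AIR split of its LPS-up genes."""

    air: dict[str, set[str]]
    not_air: dict[str, set[str]]

    def __post_init__(self) -> None:
        for ct in self.air:
            if self.air[ct] & self.not_air.get(ct, set()):
                raise ValueError(f"{ct}: air and not_air overlap")

    @property
    def cell_types(self) -> list[str]:
        return list(self.air)

    def lps_up(self, ct: str) -> set[str]:
        return self.air[ct] | self.not_air[ct]


@dataclass
class GeneSetPartition:
    """Exclusive membership categories over named gene sets."""

    categories: dict[str, set[str]]
    set_names: list[str]

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.categories.items()}

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.categories.values())


def call_regulation(de: pd.DataFrame, params: AnalysisParams) -> pd.DataFrame:
    """Up/down/unchanged calls per (gene, cell_type, contrast) with relaxation.

    A gene is significant-up when q < q_threshold and log2fc > 0 (symmetric
    for down).  The relaxation pass then marks a gene as regulated
    (basis='relaxed') in any cell type where its linear fold-change is
    strictly greater than ``relax_fc`` in the same direction, provided it
    is significant in at least one *other* cell type for the same contrast
    and direction.
    """
    de = de.copy()
    sig = de["qvalue"] < params.q_threshold
    up = sig & (de["log2fc"] > 0)
    down = sig & (de["log2fc"] < 0)
    call = np.where(up, "up", np.where(down, "down", "unchanged"))
    basis = np.where(up | down, "significant", "none")
    de["call"] = call
    de["basis"] = basis

    log_relax = math.log2(params.relax_fc)
    for contrast, sub in de.groupby("contrast", sort=False):
        for direction, sign in (("up", 1.0), ("down", -1.0)):
            sig_rows = sub[(sub["call"] == direction) & (sub["basis"] == "significant")]
            anchors = sig_rows.groupby("gene")["cell_type"].agg(set)
            if anchors.empty:
                continue
            cand = sub[
                (sub["call"] == "unchanged")
                & (sign * sub["log2fc"] > log_relax)
                & sub["gene"].isin(anchors.index)
            ]
            for row in cand.itertuples():
                # anchor must be a different cell type
                if anchors[row.gene] - {row.cell_type}:
                    de.loc[row.Index, "call"] = direction
                    de.loc[row.Index, "basis"] = "relaxed"
    cols = ["gene", "cell_type", "contrast", "log2fc", "qvalue", "call", "basis"]
    if "base_mean" in de.columns:
        cols.insert(3, "base_mean")
    return de[cols]


def regulated_sets(
    regulation: pd.DataFrame, contrast: str, direction: str = "up"
) -> dict[str, set[str]]:
    """Per-cell-type gene sets with the given call for one contrast."""
    sub = regulation[(regulation["contrast"] == contrast)
                     & (regulation["call"] == direction)]
    out: dict[str, set[str]] = {
        ct: set() for ct in regulation["cell_type"].unique()
    }
    for ct, grp in sub.groupby("cell_type"):
        out[ct] = set(grp["gene"])
    return out


def classify_air(
    lps_up: dict[str, set[str]],
    cond_means: pd.DataFrame,
    params: AnalysisParams,
    responsive: dict[str, bool] | None = None,
) -> AIRPartition:
    """Split each cell type's LPS-up genes into AIR and not-AIR.

    AIR genes decline at least ``air_fc``-fold (inclusive) when IL-10
    pre-treatment is added to LPS:
    ``(mean_LPS + pc) / (mean_IL10_LPS + pc) >= air_fc``.  Cell types
    flagged non-IL-10-responsive (eosinophils by default) are excluded
    from the partition entirely.
    """
    responsive = responsive or {}
    pc = params.pseudocount
    wide = cond_means.pivot_table(
        index=["gene", "cell_type"], columns="treatment", values="mean"
    )
    lps_mean = wide["LPS"].to_dict() if "LPS" in wide else {}
    both_mean = wide["IL10_LPS"].to_dict() if "IL10_LPS" in wide else {}
    air: dict[str, set[str]] = {}
    not_air: dict[str, set[str]] = {}
    for ct, genes in lps_up.items():
        if not responsive.get(ct, True):
            continue
        air[ct], not_air[ct] = set(), set()
        for gene in genes:
            key = (gene, ct)
            if key not in lps_mean or key not in both_mean:
                continue
            ratio = (lps_mean[key] + pc) / (both_mean[key] + pc)
            (air if ratio >= params.air_fc else not_air)[ct].add(gene)
    return AIRPartition(air=air, not_air=not_air)


def il10_up_sets(
    regulation: pd.DataFrame, contrast: str = "IL10_vs_ctrl"
) -> dict[str, set[str]]:
    """Per-cell-type sets of genes up-regulated by IL-10 alone."""
    return regulated_sets(regulation, contrast, "up")


def venn_partition(sets: dict[str, set[str]]) -> GeneSetPartition:
    """Exclusive categories: unique-to-X, exactly-2, ..., all-k.

    Every member of the union lands in exactly one category, determined by
    how many input sets contain it; singles are split by which set.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets to partition")
    names = list(sets)
    k = len(names)
    categories: dict[str, set[str]] = {f"unique-{n}": set() for n in names}
    for m in range(2, k):
        categories[f"exactly-{m}"] = set()
    categories[f"all-{k}"] = set()
    union = set().union(*sets.values())
    for gene in union:
        members = [n for n in names if gene in sets[n]]
        if len(members) == 1:
            categories[f"unique-{members[0]}"].add(gene)
        elif len(members) == k:
            categories[f"all-{k}"].add(gene)
        else:
            categories[f"exactly-{len(members)}"].add(gene)
    return GeneSetPartition(categories=categories, set_names=names)


def celltype_specific_air(partition: AIRPartition) -> dict[str, set[str]]:
    """AIR sets with every gene that is AIR in >= 2 cell types removed."""
    if len(partition.air) < 2:
        raise ValueError("need AIR sets for at least 2 cell types")
    counts: dict[str, int] = {}
    for genes in partition.air.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    shared = {g for g, c in counts.items() if c >= 2}
    return {ct: genes - shared for ct, genes in partition.air.items()}


def mark_relaxed_targets(
    de: pd.DataFrame,
    gene_list: list[str],
    contrast: str,
    fc: float = 1.5,
) -> pd.DataFrame:
    """Star-marking: linear FC >= fc (inclusive) per gene and cell type.

    Genes absent from the DE tables are recorded as missing (NaN), never
    as False.
    """
    sub = de[de["contrast"] == contrast]
    cell_types = sorted(sub["cell_type"].unique())
    log_fc = math.log2(fc)
    out = pd.DataFrame(index=pd.Index(gene_list, name="gene"),
                       columns=cell_types, dtype=object)
    lookup = sub.set_index(["gene", "cell_type"])["log2fc"]
    for gene in gene_list:
        for ct in cell_types:
            try:
                out.loc[gene, ct] = bool(lookup.loc[(gene, ct)] >= log_fc)
            except KeyError:
                out.loc[gene, ct] = np.nan
    return out
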