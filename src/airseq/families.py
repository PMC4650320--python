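"""Cytokine/chemokine family-level summaries.

Genes carry zero or more family labels (interleukins, chemokines, TNF
members, ...; up to 20 families).  Three views are computed: the
distribution of a family's fold-changes against the rest of the expressed
transcriptome (rank test), cytokines shared across cell types ordered by
overall fold-change, and focused IRF / NF-kB family expression-change
summaries for the IL-10-on-LPS contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AnalysisParams
from .stats import mann_whitney, significance_flag


@dataclass
class FamilyTestResult:
    family: str
    cell_type: str
    contrast: str
    n_members: int
    n_background: int
    median_log2fc: float
    background_median: float
    u_statistic: float | None
    pvalue: float | None
    flag: str


def family_fc_test(
    de: pd.DataFrame,
    family_table: pd.DataFrame,
    family: str,
    contrast: str,
    cell_type: str,
    params: AnalysisParams | None = None,
) -> FamilyTestResult:
    """Rank-test a family's log2 fold-changes against the transcriptome.

    Only expressed genes (base_mean >= expression_floor) enter either side;
    with fewer than 3 expressed members the test is recorded as not
    computed.
    """
    params = params or AnalysisParams()
    sub = de[(de["contrast"] == contrast) & (de["cell_type"] == cell_type)
             & (de["base_mean"] >= params.expression_floor)]
    members = set(family_table.loc[family_table["family"] == family, "gene"])
    fam_fc = sub.loc[sub["gene"].isin(members), "log2fc"].to_numpy()
    bg_fc = sub.loc[~sub["gene"].isin(members), "log2fc"].to_numpy()
    if fam_fc.size < 3 or bg_fc.size < 3:
        return FamilyTestResult(family, cell_type, contrast, fam_fc.size,
                                bg_fc.size, float(np.median(fam_fc)) if fam_fc.size else np.nan,
                                float(np.median(bg_fc)) if bg_fc.size else np.nan,
                                None, None, "not-computed")
    u, p = mann_whitney(fam_fc, bg_fc, alternative="two-sided")
    return FamilyTestResult(
        family=family, cell_type=cell_type, contrast=contrast,
        n_members=int(fam_fc.size), n_background=int(bg_fc.size),
        median_log2fc=float(np.median(fam_fc)),
        background_median=float(np.median(bg_fc)),
        u_statistic=u, pvalue=p, flag=significance_flag(p, params.mwu_alpha),
    )


def shared_cytokines(
    regulation: pd.DataFrame,
    family_table: pd.DataFrame,
    contrast: str = "LPS_vs_ctrl",
    min_celltypes: int = 2,
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """Family-annotated genes up-regulated in >= min_celltypes cell types,
    ordered by overall fold-change (mean log2fc over expressed cell types),
    descending."""
    params = params or AnalysisParams()
    annotated = set(family_table["gene"])
    sub = regulation[regulation["contrast"] == contrast]
    up = sub[(sub["call"] == "up") & sub["gene"].isin(annotated)]
    n_up = up.groupby("gene")["cell_type"].nunique()
    keep = set(n_up[n_up >= min_celltypes].index)
    if not keep:
        return pd.DataFrame(columns=["gene", "families", "n_celltypes_up",
                                     "overall_log2fc"])
    expressed = sub[sub["gene"].isin(keep)]
    if "base_mean" in expressed.columns:
        expressed = expressed[expressed["base_mean"] >= params.expression_floor]
    overall = expressed.groupby("gene")["log2fc"].mean().rename("overall_log2fc")
    fam_join = (
        family_table[family_table["gene"].isin(keep)]
        .groupby("gene")["family"]
        .agg(lambda s: ",".join(sorted(set(s))))
        .rename("families")
    )
    out = pd.concat([fam_join, n_up[n_up >= min_celltypes].rename("n_celltypes_up"),
                     overall], axis=1).reset_index()
    return out.sort_values(["overall_log2fc", "gene"],
                           ascending=[False, True]).reset_index(drop=True)


def tf_family_changes(
    de: pd.DataFrame,
    tf_families: dict[str, list[str]],
    contrast: str = "IL10_LPS_vs_LPS",
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """IRF / NF-kB member fold-changes per cell type with a family median.

    A family is down-flagged in a cell type when its median linear
    fold-change falls below 1/relax_fc.  Members absent from the DE tables
    are listed as missing; an empty family is an error record.
    """
    params = params or AnalysisParams()
    sub = de[de["contrast"] == contrast]
    lookup = sub.set_index(["gene", "cell_type"])["log2fc"]
    down_cut = -math.log2(params.relax_fc)
    rows = []
    for fam, members in tf_families.items():
        if not members:
            rows.append({"family": fam, "cell_type": "", "gene": "",
                         "log2fc": np.nan, "family_median_log2fc": np.nan,
                         "down_flag": False, "status": "error-empty-family"})
            continue
        for ct in sorted(sub["cell_type"].unique()):
            fcs = {}
            for gene in members:
                try:
                    fcs[gene] = float(lookup.loc[(gene, ct)])
                except KeyError:
                    fcs[gene] = np.nan
            present = [v for v in fcs.values() if not np.isnan(v)]
            med = float(np.median(present)) if present else np.nan
            flag = bool(present) and med < down_cut
            for gene, fc in fcs.items():
                rows.append({
                    "family": fam, "cell_type": ct, "gene": gene,
                    "log2fc": fc, "family_median_log2fc": med,
                    "down_flag": flag,
                    "status": "ok" if not np.isnan(fc) else "missing",
                })
    return pd.DataFrame(rows)
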