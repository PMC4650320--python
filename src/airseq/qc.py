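"""Sample-structure QC and dimensionality reduction.

Replicate Pearson correlations (libraries below r = 0.7 are flagged),
pairwise R-squared clustering of all samples, and PCA of the
log2(normalised count + 1) expression matrix with per-component
treatment association.  In the real libraries cell identity dominates the
variance and an LPS-associated component only appears deep in the
spectrum (PC6), with no IL-10 component at all; the PCA here reports a
point-biserial correlation of every component's scores with the LPS and
IL-10 indicators so that observation is directly reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .de import normalized_counts
from .model import AnalysisParams, CountMatrix
from .stats import point_biserial

QC_CORR_FLOOR = 0.7


def log_expression(
    cm: CountMatrix, sf: pd.Series, params: AnalysisParams | None = None,
    expressed_only: bool = False,
) -> pd.DataFrame:
    """log2(normalised count + 1), optionally restricted to expressed genes."""
    params = params or AnalysisParams()
    norm = normalized_counts(cm, sf)
    if expressed_only:
        norm = norm[norm.mean(axis=1) >= params.expression_floor]
    return np.log2(norm + 1.0)


def replicate_correlation(cm: CountMatrix, sf: pd.Series) -> pd.DataFrame:
    """Pearson r on log expression for every within-group replicate pair."""
    logx = log_expression(cm, sf)
    rows = []
    for (ct, tr), sample_ids in cm.groups().items():
        for a, b in itertools.combinations(sample_ids, 2):
            r = float(np.corrcoef(logx[a], logx[b])[0, 1])
            rows.append({"cell_type": ct, "treatment": tr, "sample_a": a,
                         "sample_b": b, "pearson_r": r,
                         "qc_flag": r < QC_CORR_FLOOR})
    if not rows:
        return pd.DataFrame(columns=["cell_type", "treatment", "sample_a",
                                     "sample_b", "pearson_r", "qc_flag"])
    return pd.DataFrame(rows)


def r2_matrix(cm: CountMatrix, sf: pd.Series) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise R^2 on log expression + average-linkage leaf order on 1 - R^2.

    Constant samples (zero variance) yield undefined correlations and are
    recorded as NaN off-diagonal.
    """
    if len(cm.samples) < 3:
        raise ValueError("R^2 clustering needs >= 3 samples")
    logx = log_expression(cm, sf).to_numpy()
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(logx.T)
    r2 = corr**2
    np.fill_diagonal(r2, 1.0)
    df = pd.DataFrame(r2, index=cm.sample_ids, columns=cm.sample_ids)
    dist = 1.0 - np.nan_to_num(r2, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    order = leaves_list(average(squareform(dist, checks=False)))
    return df, [cm.sample_ids[i] for i in order]


@dataclass
class PCAResult:
    scores: pd.DataFrame                 # samples x components
    loadings: pd.DataFrame               # genes x components
    explained_variance_ratio: np.ndarray
    treatment_association: pd.DataFrame  # per component: r_lps, r_il10
    lps_axis: int | None                 # 1-based component index, or None
    il10_axis: int | None
    top_loading_genes: dict[str, list[str]] = field(default_factory=dict)


def pca_treatment_axis(
    cm: CountMatrix,
    sf: pd.Series,
    params: AnalysisParams | None = None,
    assoc_threshold: float = 0.7,
    n_top_genes: int = 50,
) -> PCAResult:
    """PCA of log expression with detection of treatment-associated axes.

    Components are numbered from 1.  For each component the scores are
    correlated (point-biserial) with the LPS indicator (treatment in
    {LPS, IL10_LPS}) and the IL-10 indicator (treatment in
    {IL10, IL10_LPS}); the treatment axis is the lowest-index component
    whose |r| exceeds ``assoc_threshold``, or None — the absence of an
    IL-10 axis is itself an observable outcome.  Loading signs are fixed
    by forcing the largest-magnitude loading positive.
    """
    params = params or AnalysisParams()
    logx = log_expression(cm, sf, params, expressed_only=True)
    x = logx.to_numpy().T  # samples x genes
    pca = PCA(n_components=min(x.shape))
    scores = pca.fit_transform(x)
    loadings = pca.components_.T  # genes x components
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0

    meta = cm.meta_frame()
    lps = meta["treatment"].isin(["LPS", "IL10_LPS"]).to_numpy().astype(float)
    il10 = meta["treatment"].isin(["IL10", "IL10_LPS"]).to_numpy().astype(float)
    comps = [f"PC{k+1}" for k in range(scores.shape[1])]
    assoc = pd.DataFrame({
        "component": comps,
        "r_lps": [point_biserial(scores[:, k], lps) for k in range(len(comps))],
        "r_il10": [point_biserial(scores[:, k], il10) for k in range(len(comps))],
    })

    def first_axis(col: str) -> int | None:
        hit = assoc.index[assoc[col].abs() > assoc_threshold]
        return int(hit[0]) + 1 if len(hit) else None

    lps_axis = first_axis("r_lps")
    top: dict[str, list[str]] = {}
    for k, comp in enumerate(comps):
        ranked = np.argsort(-loadings[:, k])[:n_top_genes]
        top[comp] = [logx.index[i] for i in ranked]
    return PCAResult(
        scores=pd.DataFrame(scores, index=cm.sample_ids, columns=comps),
        loadings=pd.DataFrame(loadings, index=logx.index, columns=comps),
        explained_variance_ratio=pca.explained_variance_ratio_,
        treatment_association=assoc,
        lps_axis=lps_axis,
        il10_axis=first_axis("r_il10"),
        top_loading_genes=top,
    )
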