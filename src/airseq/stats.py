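"""Shared statistical helpers: BH FDR and Mann-Whitney U."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values cannot be BH-adjusted")
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney(
    x, y, alternative: str = "two-sided", method: str = "auto"
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of x, p).

    ``method='auto'`` uses the exact distribution for small untied samples
    and the tie- and continuity-corrected normal approximation otherwise,
    matching common practice for promoter-level rank comparisons.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def significance_flag(p: float, alpha_pair: tuple[float, float] = (0.05, 0.01)) -> str:
    """'**' below the stricter level, '*' below the looser, else 'n.s.'."""
    loose, strict = max(alpha_pair), min(alpha_pair)
    if p < strict:
        return "**"
    if p < loose:
        return "*"
    return "n.s."


def point_biserial(scores: np.ndarray, indicator: np.ndarray) -> float:
    """Pearson correlation between a continuous score and a 0/1 indicator."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(indicator, dtype=float)
    sx, sy = x.std(), y.std()
    # components with (near-)constant scores carry no treatment signal
    if sy == 0 or sx < 1e-10 * max(1.0, np.abs(x).max()):
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
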