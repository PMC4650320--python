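"""Best-hit PWM enrichment on TSS-proximal promoter windows.

Each promoter is summarised by its best log-odds PWM hit over every offset
and both strands, min-max normalised to [0, 1] by the PWM's attainable
extremes.  A gene set is called enriched for a motif when its mean best-hit
score exceeds the promoter-background mean by a one-sided z-test
(z = (mean_fg - mean_bg) / (sd_bg / sqrt(n_fg))), BH-corrected across the
PWM library.  The background is the full set of analysed promoters, not
the genome, so ubiquitous TSS-proximal motifs (the classic AP-1 caveat)
show up as high background means rather than spurious enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats as sps

from .classify import AIRPartition
from .model import PWM, PromoterWindow
from .stats import bh_qvalues

EPSILON = 1e-3  # probability floor before taking log-odds

_CODE = {b: i for i, b in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[b] for b in seq), dtype=np.int8, count=len(seq))


def _log_odds(pwm: PWM) -> np.ndarray:
    probs = np.clip(pwm.matrix, EPSILON, None)
    return np.log2(probs / pwm.background[None, :])


def best_score(pwm: PWM, window: PromoterWindow | str) -> float | None:
    """Best normalised log-odds hit over all offsets and both strands.

    Subsequences containing N are skipped.  The raw best score is mapped to
    [0, 1] via the PWM's attainable extremes; a degenerate PWM whose
    extremes coincide (e.g. the uniform matrix against a uniform
    background) scores 0.5 by convention.  Returns None when the window is
    shorter than the PWM or no N-free subwindow exists.
    """
    seq = window.sequence if isinstance(window, PromoterWindow) else window
    w = pwm.width
    if len(seq) < w:
        return None
    lo = _log_odds(pwm)
    s_min, s_max = float(lo.min(axis=1).sum()), float(lo.max(axis=1).sum())
    codes = _encode(seq)
    # reverse-complement scan == scanning the forward sequence with the
    # reverse-complemented matrix
    lo_rc = lo[::-1, ::-1]
    views = sliding_window_view(codes, w)          # (n_offsets, w)
    valid = (views != 4).all(axis=1)
    if not valid.any():
        return None
    sub = views[valid]
    cols = np.arange(w)
    fwd = lo[cols, sub].sum(axis=1)
    rev = lo_rc[cols, sub].sum(axis=1)
    raw = float(max(fwd.max(), rev.max()))
    if s_max - s_min < 1e-12:
        return 0.5
    return (raw - s_min) / (s_max - s_min)


def score_matrix(
    pwms: list[PWM], windows: dict[str, PromoterWindow]
) -> pd.DataFrame:
    """Best-hit scores, genes x PWMs; NaN where a window was unscorable."""
    genes = list(windows)
    data = np.full((len(genes), len(pwms)), np.nan)
    for j, pwm in enumerate(pwms):
        for i, gene in enumerate(genes):
            s = best_score(pwm, windows[gene])
            if s is not None:
                data[i, j] = s
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"),
                        columns=[p.id for p in pwms])


@dataclass
class EnrichmentResult:
    pwm_id: str
    n_fg: int
    mean_fg: float
    mean_bg: float
    sd_bg: float
    z: float
    pvalue: float
    qvalue: float = float("nan")
    side: str = ""
    cell_type: str = ""
    degenerate: bool = False


def enrich(
    pwm_id: str,
    fg_scores: np.ndarray,
    bg_scores: np.ndarray,
    min_fg: int = 5,
) -> EnrichmentResult:
    """One-sided z-test of a foreground's mean best-hit score vs background."""
    fg = np.asarray(fg_scores, dtype=float)
    bg = np.asarray(bg_scores, dtype=float)
    fg, bg = fg[~np.isnan(fg)], bg[~np.isnan(bg)]
    if fg.size < min_fg:
        raise ValueError(f"foreground must have >= {min_fg} scorable promoters")
    mean_fg, mean_bg = float(fg.mean()), float(bg.mean())
    sd_bg = float(bg.std(ddof=1))
    if sd_bg == 0:
        return EnrichmentResult(pwm_id, fg.size, mean_fg, mean_bg, 0.0,
                                z=0.0, pvalue=1.0, degenerate=True)
    z = (mean_fg - mean_bg) / (sd_bg / np.sqrt(fg.size))
    p = float(sps.norm.sf(z))
    return EnrichmentResult(pwm_id, fg.size, mean_fg, mean_bg, sd_bg,
                            z=float(z), pvalue=max(p, np.nextafter(0, 1)))


def enrich_library(
    scores: pd.DataFrame, fg_genes: set[str], min_fg: int = 5
) -> pd.DataFrame:
    """Run enrich for every PWM in a score matrix; BH across the library."""
    fg_idx = scores.index.isin(fg_genes)
    if fg_idx.sum() < min_fg:
        raise ValueError("too few foreground genes with scorable promoters")
    rows = []
    for pwm_id in scores.columns:
        res = enrich(pwm_id, scores.loc[fg_idx, pwm_id].to_numpy(),
                     scores[pwm_id].to_numpy(), min_fg=min_fg)
        rows.append(res)
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["qvalue"] = bh_qvalues(out["pvalue"].to_numpy())
    return out


def enrich_partition(
    pwms: list[PWM],
    partition: AIRPartition,
    windows: dict[str, PromoterWindow],
    min_fg: int = 5,
) -> pd.DataFrame:
    """Motif enrichment for the AIR and not-AIR side of every cell type.

    The background is always the full promoter universe supplied in
    ``windows``.  Sides with too few scorable promoters are skipped and
    recorded with NaN statistics.
    """
    usable = {g: w for g, w in windows.items() if not w.truncated}
    scores = score_matrix(pwms, usable)
    frames = []
    for ct in partition.cell_types:
        for side, genes in (("AIR", partition.air[ct]),
                            ("not-AIR", partition.not_air[ct])):
            present = genes & set(usable)
            if len(present) < min_fg:
                frames.append(pd.DataFrame([{
                    "pwm_id": p.id, "n_fg": len(present), "mean_fg": np.nan,
                    "mean_bg": np.nan, "sd_bg": np.nan, "z": np.nan,
                    "pvalue": np.nan, "qvalue": np.nan, "side": side,
                    "cell_type": ct, "degenerate": False,
                } for p in pwms]))
                continue
            res = enrich_library(scores, present, min_fg=min_fg)
            res["side"] = side
            res["cell_type"] = ct
            frames.append(res)
    return pd.concat(frames, ignore_index=True)
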