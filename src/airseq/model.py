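"""Core domain types shared by every stage of the pipeline.

The analysis revolves around a 5 cell-type x 4 treatment design: myeloid
cells (macrophages, neutrophils, splenic dendritic cells, mast cells,
eosinophils) are pre-treated with IL-10 for 4 h and/or stimulated with LPS
for 4 h.  Everything downstream consumes a :class:`CountMatrix` of raw gene
counts plus per-sample metadata, and the thresholds collected in
:class:`AnalysisParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CELL_TYPES = ("macrophage", "neutrophil", "sDC", "mast", "eosinophil")
TREATMENTS = ("ctrl", "IL10", "LPS", "IL10_LPS")

#: The three two-group contrasts the design supports, all within cell type:
#: the LPS pro-inflammatory response, the IL-10 program, and the IL-10
#: suppression of the LPS response.
CONTRASTS = {
    "LPS_vs_ctrl": ("ctrl", "LPS"),
    "IL10_vs_ctrl": ("ctrl", "IL10"),
    "IL10_LPS_vs_LPS": ("LPS", "IL10_LPS"),
}


class FormatError(ValueError):
    """Malformed input file (bad header, duplicate ids, non-numeric cells)."""


class ConsistencyError(ValueError):
    """Inputs that are individually valid but mutually inconsistent."""


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing library: which cells, which treatment, which mouse."""

    sample_id: str
    cell_type: str
    treatment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise FormatError(f"unknown cell type {self.cell_type!r}")
        if self.treatment not in TREATMENTS:
            raise FormatError(f"unknown treatment {self.treatment!r}")
        if self.replicate < 1:
            raise FormatError("replicate must be a positive integer")

    @property
    def group(self) -> tuple[str, str]:
        return (self.cell_type, self.treatment)


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with sample metadata.

    ``counts`` is a genes x samples DataFrame whose columns follow
    ``samples`` order exactly.
    """

    counts: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ConsistencyError("duplicate sample ids")
        if list(self.counts.columns) != ids:
            raise ConsistencyError("count columns do not match sample sheet order")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric counts")
        if not np.isfinite(values).all() or (values < 0).any():
            raise FormatError("counts must be finite and >= 0")
        reps: dict[tuple[str, str], set[int]] = {}
        for s in self.samples:
            seen = reps.setdefault(s.group, set())
            if s.replicate in seen:
                raise ConsistencyError(
                    f"replicate {s.replicate} duplicated in group {s.group}"
                )
            seen.add(s.replicate)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "cell_type": [s.cell_type for s in self.samples],
                "treatment": [s.treatment for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        ).set_index("sample_id")

    def groups(self) -> dict[tuple[str, str], list[str]]:
        """(cell_type, treatment) -> sample ids, in sheet order."""
        out: dict[tuple[str, str], list[str]] = {}
        for s in self.samples:
            out.setdefault(s.group, []).append(s.sample_id)
        return out

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        keep = set(sample_ids)
        samples = [s for s in self.samples if s.sample_id in keep]
        return CountMatrix(self.counts[[s.sample_id for s in samples]], samples)


@dataclass(frozen=True)
class AnalysisParams:
    """Thresholds and window geometry used throughout the analysis.

    Defaults mirror the published analysis: DE significance at BH q < 0.1,
    cross-cell-type relaxation at linear fold-change > 1.5, AIR suppression
    at >= 2-fold decline, promoters taken as [TSS-450, TSS+50), and a CpG
    reference frequency of 0.75 drawn as a guide line in outputs.
    """

    q_threshold: float = 0.1
    relax_fc: float = 1.5
    air_fc: float = 2.0
    promoter_upstream: int = 450
    promoter_downstream: int = 50
    cpg_ref_freq: float = 0.75
    pseudocount: float = 1.0
    mwu_alpha: tuple[float, float] = (0.05, 0.01)
    expression_floor: float = 5.0

    def __post_init__(self) -> None:
        for name in ("q_threshold", "relax_fc", "air_fc",
                     "promoter_upstream", "promoter_downstream"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @property
    def window_length(self) -> int:
        return self.promoter_upstream + self.promoter_downstream

    def with_overrides(self, **kwargs) -> "AnalysisParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GeneAnnotation:
    """TSS anchor for a gene's promoter window."""

    gene: str
    sequence_id: str
    tss: int
    strand: str
    families: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise FormatError("tss must be a non-negative 0-based coordinate")


@dataclass
class PWM:
    """Position weight matrix over A,C,G,T with a background model.

    ``matrix`` is width x 4, every row a probability distribution.
    """

    id: str
    name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise FormatError(f"PWM {self.id}: matrix must be w x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise FormatError(f"PWM {self.id}: rows must sum to 1")
        if (self.matrix < 0).any():
            raise FormatError(f"PWM {self.id}: negative probabilities")

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def information_content(self) -> float:
        """Mean information content per column, in bits."""
        p = np.clip(self.matrix, 1e-12, None)
        return float(np.mean(2.0 + (p * np.log2(p)).sum(axis=1)))


@dataclass
class PromoterWindow:
    """Strand-oriented promoter sequence around the TSS (5'->3' of the gene)."""

    gene: str
    sequence: str
    truncated: bool = False

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise FormatError(f"promoter {self.gene}: invalid characters {bad}")
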