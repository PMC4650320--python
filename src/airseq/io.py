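"""Readers and writers for the plain-text formats the pipeline touches.

Counts and sample sheets are TSV, promoters are FASTA plus a 6-column
BED-like table, motifs are JASPAR-style text, cytokine families a two-column
TSV.  Readers validate invariants up front and never silently drop records;
each reader is the inverse of the matching writer on canonical files.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    ConsistencyError,
    CountMatrix,
    FormatError,
    GeneAnnotation,
    PWM,
    SampleMeta,
)

SHEET_COLUMNS = ["sample_id", "cell_type", "treatment", "replicate"]


# ---------------------------------------------------------------------------
# counts + sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns {missing}")
    return [
        SampleMeta(
            sample_id=row.sample_id,
            cell_type=row.cell_type,
            treatment=row.treatment,
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]


def read_counts(path: str | Path, sample_sheet: str | Path) -> CountMatrix:
    """Load a gene x sample TSV and its sample sheet into a CountMatrix.

    The first column of the TSV must be named ``gene``; remaining columns
    are sample ids.  Every sample in the sheet must be present in the
    matrix (extra matrix columns are an error too, so that no library is
    silently ignored).
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene":
        raise FormatError("first column of a counts TSV must be 'gene'")
    df = df.set_index("gene")
    samples = read_sample_sheet(sample_sheet)
    sheet_ids = [s.sample_id for s in samples]
    absent = sorted(set(sheet_ids) - set(df.columns))
    if absent:
        raise ConsistencyError(f"samples in sheet absent from matrix: {absent}")
    extra = sorted(set(df.columns) - set(sheet_ids))
    if extra:
        raise ConsistencyError(f"matrix columns not in sample sheet: {extra}")
    counts = df[sheet_ids]
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr).all():
        raise FormatError("counts must be numeric and finite")
    if not np.allclose(arr, np.round(arr)):
        raise FormatError("counts must be integers")
    return CountMatrix(counts.round().astype(np.int64), samples)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def write_sample_sheet(cm: CountMatrix, path: str | Path) -> None:
    cm.meta_frame().reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PWMs (JASPAR-style)
# ---------------------------------------------------------------------------

def read_pwms(
    path: str | Path,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> list[PWM]:
    """Parse a JASPAR-style motif file into probability-normalised PWMs.

    Each motif is a ``>ID NAME`` header followed by four rows (A, C, G, T)
    of per-position counts or probabilities.  Columns are regularised as
    ``(c + pseudocount) / (sum + 4 * pseudocount)`` so that no probability
    is exactly zero; an all-zero column is a format error.
    """
    try:
        with open(path) as handle:
            parsed = bio_motifs.parse(handle, "jaspar")
            records = [(m.matrix_id, m.name, m.counts) for m in parsed]
    except Exception as exc:  # biopython raises bare Exceptions on bad input
        raise FormatError(f"cannot parse PWM file {path}: {exc}") from exc
    pwms = []
    for matrix_id, name, counts in records:
        mat = np.array([counts[b] for b in "ACGT"], dtype=float).T  # w x 4
        if mat.size == 0:
            raise FormatError(f"PWM {matrix_id}: empty matrix")
        col_sums = mat.sum(axis=1)
        if (col_sums <= 0).any():
            raise FormatError(f"PWM {matrix_id}: column of all zeros")
        probs = (mat + pseudocount) / (col_sums + 4 * pseudocount)[:, None]
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        pwms.append(PWM(id=matrix_id, name=name or matrix_id, matrix=probs, background=bg))
    if not pwms:
        raise FormatError(f"no motifs found in {path}")
    return pwms


def write_pwms(pwms: list[PWM], path: str | Path, scale: int = 100) -> None:
    """Write PWMs as JASPAR-style integer count matrices (probabilities x scale)."""
    with open(path, "w") as out:
        for pwm in pwms:
            out.write(f">{pwm.id} {pwm.name}\n")
            counts = np.round(pwm.matrix * scale).astype(int)
            for i, base in enumerate("ACGT"):
                row = " ".join(str(v) for v in counts[:, i])
                out.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# promoters: FASTA + BED-like annotation
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """6-column BED-like TSV: sequence_id, start, end, gene, score, strand.

    Coordinates are 0-based half-open; the TSS is ``start`` on the + strand
    and ``end - 1`` on the - strand.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["sequence_id", "start", "end", "gene", "score", "strand"],
        dtype={"sequence_id": str, "gene": str, "strand": str},
    )
    out = []
    for row in df.itertuples():
        tss = int(row.start) if row.strand == "+" else int(row.end) - 1
        out.append(
            GeneAnnotation(
                gene=row.gene, sequence_id=row.sequence_id, tss=tss, strand=row.strand
            )
        )
    return out


def write_annotations(annots: list[GeneAnnotation], path: str | Path, span: int = 1) -> None:
    """Write TSS anchors back out as single-base BED-like features."""
    with open(path, "w") as out:
        for a in annots:
            if a.strand == "+":
                start, end = a.tss, a.tss + span
            else:
                start, end = a.tss - span + 1, a.tss + 1
            out.write(f"{a.sequence_id}\t{start}\t{end}\t{a.gene}\t0\t{a.strand}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise FormatError(f"sequence {rec.id}: invalid characters {sorted(bad)}")
        if rec.id in seqs:
            raise FormatError(f"duplicate sequence id {rec.id}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as out:
        SeqIO.write(records, out, "fasta")


def read_promoters(
    fasta_path: str | Path, annot_path: str | Path
) -> tuple[dict[str, tuple[str, GeneAnnotation]], list[str]]:
    """Pair promoter sequences with their TSS annotations.

    Returns (gene -> (uppercase sequence, annotation), missing) where
    ``missing`` lists genes annotated but absent from the FASTA — reported,
    never silently dropped.
    """
    seqs = read_fasta(fasta_path)
    annots = read_annotations(annot_path)
    paired: dict[str, tuple[str, GeneAnnotation]] = {}
    missing: list[str] = []
    for a in annots:
        if a.sequence_id not in seqs:
            missing.append(a.gene)
            continue
        paired[a.gene] = (seqs[a.sequence_id], a)
    return paired, missing


# ---------------------------------------------------------------------------
# cytokine family table
# ---------------------------------------------------------------------------

def read_family_table(path: str | Path) -> pd.DataFrame:
    """Long-format gene -> family TSV; a gene may carry several labels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "family"):
        if col not in df.columns:
            raise FormatError(f"family table missing column {col!r}")
    return df[["gene", "family"]]


def write_family_table(table: pd.DataFrame, path: str | Path) -> None:
    table[["gene", "family"]].to_csv(path, sep="\t", index=False)


def canonical_counts_bytes(cm: CountMatrix) -> bytes:
    """Canonical byte representation of a count matrix (round-trip oracle)."""
    buf = _io.StringIO()
    out = cm.counts.copy()
    out.index.name = "gene"
    out.to_csv(buf, sep="\t")
    return buf.getvalue().encode()
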