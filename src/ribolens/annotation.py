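"""Per-gene annotation tables built on the principal (most abundant) transcript.

All downstream length analyses use one transcript per gene: the transcript
with the highest TPM in the reference tissue.  This module selects that
transcript, computes CDS GC content, assembles the per-gene table
(transcript/CDS/UTR lengths, GC, abundance) and applies the high-confidence
expression filter (strictly greater than a FPKM threshold).

Coordinates are 0-based half-open throughout; GTF input is converted at the
reader boundary (:func:`ribolens.io.read_gtf_models`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_TABLE_COLUMNS = [
    "gene_id",
    "principal_transcript",
    "transcript_length",
    "cds_length",
    "utr5_length",
    "utr3_length",
    "gene_length",
    "gc_cds",
    "tpm",
    "fpkm",
    "flag",
]


@dataclass
class TranscriptModel:
    """One transcript of a gene model.

    ``coding_start`` is the genomic coordinate (0-based) of the first CDS
    base *in transcription order*: the leftmost CDS base on the plus strand,
    the rightmost on the minus strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    transcript_start: int
    transcript_end: int
    coding_start: int
    exon_intervals: list[tuple[int, int]] = field(default_factory=list)
    cds_length: int = 0
    utr3_length: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.transcript_end <= self.transcript_start:
            raise ValueError(
                f"{self.transcript_id}: transcript_end must exceed transcript_start"
            )
        span = self.transcript_end - self.transcript_start
        if not (0 <= self.cds_length <= span):
            raise ValueError(
                f"{self.transcript_id}: cds_length {self.cds_length} outside [0, span={span}]"
            )
        exons = sorted(self.exon_intervals)
        for (a, b), (c, d) in zip(exons, exons[1:]):
            if c < b:
                raise ValueError(f"{self.transcript_id}: overlapping exon intervals")
        self.exon_intervals = exons

    @property
    def exonic_length(self) -> int:
        """Mature transcript length (sum of exon lengths)."""
        if self.exon_intervals:
            return sum(b - a for a, b in self.exon_intervals)
        return self.transcript_end - self.transcript_start

    @property
    def span(self) -> int:
        """Genomic footprint including introns."""
        return self.transcript_end - self.transcript_start

    def utr5_length_annotated(self) -> int:
        """Exonic distance from the annotated transcript start to the coding start."""
        exons = self.exon_intervals or [(self.transcript_start, self.transcript_end)]
        if self.strand == "+":
            return sum(
                min(b, self.coding_start) - a for a, b in exons if a < self.coding_start
            )
        return sum(
            b - max(a, self.coding_start + 1)
            for a, b in exons
            if b > self.coding_start + 1
        )


def select_principal_transcript(abundance: pd.DataFrame) -> dict[str, str]:
    """Pick the most abundant transcript per gene.

    Parameters
    ----------
    abundance
        Table with columns ``transcript_id``, ``gene_id``, ``tpm``.

    Returns
    -------
    dict mapping gene_id -> transcript_id with maximal TPM.  Ties (including
    all-zero genes) resolve to the lexicographically smallest transcript_id,
    so the choice is reproducible.
    """
    required = {"transcript_id", "gene_id", "tpm"}
    missing = required - set(abundance.columns)
    if missing:
        raise ValueError(f"abundance table missing columns: {sorted(missing)}")
    if abundance["gene_id"].isna().any():
        bad = abundance.loc[abundance["gene_id"].isna(), "transcript_id"].tolist()
        raise ValueError(f"transcripts without gene mapping: {bad}")
    if (abundance["tpm"] < 0).any():
        raise ValueError("negative TPM values")
    ordered = abundance.sort_values(
        ["gene_id", "tpm", "transcript_id"], ascending=[True, False, True]
    )
    first = ordered.drop_duplicates("gene_id", keep="first")
    return dict(zip(first["gene_id"], first["transcript_id"]))


def compute_gc(cds_sequence: str) -> float:
    """GC fraction of a CDS, N bases excluded from numerator and denominator.

    Returns NaN for an all-N sequence (no informative bases), never zero.
    """
    if not cds_sequence:
        raise ValueError("empty CDS sequence")
    seq = cds_sequence.upper()
    counts = {base: seq.count(base) for base in "ACGT"}
    informative = sum(counts.values())
    if informative == 0:
        return math.nan
    return (counts["G"] + counts["C"]) / informative


def build_gene_table(
    models: Sequence[TranscriptModel],
    cds_sequences: Mapping[str, str] | None,
    abundance: pd.DataFrame,
    utr5_from_annotation: bool = False,
) -> pd.DataFrame:
    """Assemble the per-gene annotation table on the principal transcript.

    ``cds_sequences`` maps transcript_id -> CDS nucleotide string (may be
    ``None`` when GC content is not needed).  ``utr5_length`` stays missing
    unless ``utr5_from_annotation`` is set, in which case it is the exonic
    distance from the annotated transcript start to the coding start — a
    fallback that keeps length analyses runnable without CAGE data.

    Rows with problems (CDS sequence length inconsistent with the model,
    transcript absent from the FASTA, gene absent from the abundance table)
    are flagged in the ``flag`` column and kept; the pipeline continues.
    """
    by_tid = {m.transcript_id: m for m in models}
    principal = select_principal_transcript(abundance)
    abundance_idx = abundance.set_index("transcript_id")

    rows = []
    for gene_id in sorted(principal):
        tid = principal[gene_id]
        model = by_tid.get(tid)
        flags: list[str] = []
        if model is None:
            logger.warning("principal transcript %s has no gene model; skipped", tid)
            continue
        gc = math.nan
        if cds_sequences is not None:
            seq = cds_sequences.get(tid)
            if seq is None:
                flags.append("missing_sequence")
            else:
                if len(seq) != model.cds_length:
                    flags.append("cds_length_mismatch")
                    logger.warning(
                        "%s: CDS sequence length %d != model cds_length %d",
                        tid,
                        len(seq),
                        model.cds_length,
                    )
                gc = compute_gc(seq)
        row_ab = abundance_idx.loc[tid]
        tpm = float(row_ab["tpm"])
        fpkm = float(row_ab["fpkm"]) if "fpkm" in abundance_idx.columns else math.nan
        if tpm == 0.0:
            flags.append("zero_abundance")
        utr5 = math.nan
        if utr5_from_annotation:
            utr5 = float(model.utr5_length_annotated())
        rows.append(
            {
                "gene_id": gene_id,
                "principal_transcript": tid,
                "transcript_length": model.exonic_length,
                "cds_length": model.cds_length,
                "utr5_length": utr5,
                "utr3_length": model.utr3_length,
                "gene_length": model.span,
                "gc_cds": gc,
                "tpm": tpm,
                "fpkm": fpkm,
                "flag": ";".join(flags),
            }
        )
    table = pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
    return table.reset_index(drop=True)


def filter_expressed(
    table: pd.DataFrame, threshold: float = 2.0, column: str = "fpkm"
) -> pd.DataFrame:
    """Keep high-confidence expressed genes: ``column`` strictly above ``threshold``.

    The boundary is exclusive: a gene at exactly the threshold is dropped.
    """
    if column not in table.columns:
        raise ValueError(f"no {column!r} column in gene table")
    values = pd.to_numeric(table[column], errors="coerce")
    return table.loc[values > threshold].reset_index(drop=True)
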