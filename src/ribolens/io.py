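"""Readers and writers for the formats the pipeline exchanges.

GTF gene models (via gffutils), CDS FASTA (via pyfaidx), strand-specific
bedGraph CAGE pileups, GMT gene-set collections, and the TSV tables the
package defines (abundance, gene annotation, differential results, TSS
calls).  GTF coordinates are 1-based inclusive on disk and converted to the
package's 0-based half-open convention here, at the boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from pyfaidx import Fasta

from ribolens.annotation import GENE_TABLE_COLUMNS, TranscriptModel
from ribolens.genesets import GeneSetCollection
from ribolens.tss import CageTrack

logger = logging.getLogger(__name__)


# -- GTF gene models ---------------------------------------------------------

def read_gtf_models(path) -> list[TranscriptModel]:
    """Parse a GTF into TranscriptModel records (one per transcript)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models = []
    for tr in db.features_of_type("transcript"):
        tid = tr.attributes["transcript_id"][0]
        gid = tr.attributes["gene_id"][0]
        exons = [
            (e.start - 1, e.end) for e in db.children(tr, featuretype="exon")
        ]
        cds = [(c.start - 1, c.end) for c in db.children(tr, featuretype="CDS")]
        cds_length = sum(e - s for s, e in cds)
        if cds:
            coding_start = (
                min(s for s, _ in cds) if tr.strand == "+" else max(e for _, e in cds) - 1
            )
        else:
            coding_start = tr.start - 1 if tr.strand == "+" else tr.end - 1
        exon_iv = sorted(exons) if exons else [(tr.start - 1, tr.end)]
        utr3 = _utr3_length(exon_iv, cds, tr.strand)
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=tr.seqid,
                strand=tr.strand,
                transcript_start=tr.start - 1,
                transcript_end=tr.end,
                coding_start=coding_start,
                exon_intervals=exon_iv,
                cds_length=cds_length,
                utr3_length=utr3,
            )
        )
    return models


def _utr3_length(exons, cds, strand) -> int:
    if not cds:
        return 0
    if strand == "+":
        cds_end = max(e for _, e in cds)  # 0-based exclusive
        return sum(max(0, e - max(s, cds_end)) for s, e in exons)
    cds_start = min(s for s, _ in cds)
    return sum(max(0, min(e, cds_start) - s) for s, e in exons)


def write_gtf(models: Sequence[TranscriptModel], path) -> None:
    """Write single-exon transcript models as GTF (transcript/exon/CDS rows)."""
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.transcript_start, m.transcript_id)):
            if len(m.exon_intervals) > 1:
                raise NotImplementedError("GTF writer supports single-exon models only")
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            s1, e1 = m.transcript_start + 1, m.transcript_end  # to 1-based inclusive
            for feat, (fs, fe) in [
                ("transcript", (s1, e1)),
                ("exon", (s1, e1)),
            ]:
                fh.write(
                    f"{m.chrom}\tribolens\t{feat}\t{fs}\t{fe}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.cds_length > 0:
                if m.strand == "+":
                    cs, ce = m.coding_start + 1, m.coding_start + m.cds_length
                else:
                    cs, ce = m.coding_start - m.cds_length + 2, m.coding_start + 1
                fh.write(
                    f"{m.chrom}\tribolens\tCDS\t{cs}\t{ce}\t.\t{m.strand}\t0\t{attrs}\n"
                )


# -- FASTA -------------------------------------------------------------------

def read_cds_fasta(path) -> dict[str, str]:
    """CDS sequences keyed by transcript id."""
    fasta = Fasta(str(path))
    return {name: str(fasta[name][:]) for name in fasta.keys()}


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- bedGraph CAGE pileups ---------------------------------------------------

def read_bedgraph(path, strand: str) -> dict[tuple[str, str], CageTrack]:
    """Per-base 5'-end counts from a bedGraph, one CageTrack per chromosome.

    Interval values are assigned to every base of [start, end).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
    )
    tracks: dict[tuple[str, str], CageTrack] = {}
    for chrom, sub in df.groupby("chrom"):
        counts: dict[int, int] = {}
        for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
            for pos in range(int(start), int(end)):
                counts[pos] = counts.get(pos, 0) + int(value)
        tracks[(str(chrom), strand)] = CageTrack(chrom=str(chrom), strand=strand, counts=counts)
    return tracks


def write_bedgraph(track: CageTrack, path) -> None:
    with open(path, "w") as fh:
        for pos in sorted(track.counts):
            count = track.counts[pos]
            if count > 0:
                fh.write(f"{track.chrom}\t{pos}\t{pos + 1}\t{count}\n")


# -- GMT gene sets -----------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """GMT: one set per line — name, description, then member gene ids."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, desc, members = fields[0], fields[1], fields[2:]
            sets[name] = {m for m in members if m}
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions=descriptions)


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            desc = sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(sets[name])]) + "\n")


# -- TSV tables --------------------------------------------------------------

def read_abundance(path) -> pd.DataFrame:
    """Transcript abundance TSV: transcript_id, gene_id, tpm[, fpkm]."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    missing = {"transcript_id", "gene_id", "tpm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_gene_table(table: pd.DataFrame, path) -> None:
    table.reindex(columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "principal_transcript": str})


def write_tss_bed(calls: pd.DataFrame, path, strand_by_gene: Mapping[str, str] | None = None) -> None:
    """BED6 of called TSS positions (name = gene_id, score = pileup height)."""
    called = calls[calls["status"] == "called"]
    with open(path, "w") as fh:
        for _, row in called.iterrows():
            chrom = row.get("chrom", "chr1")
            pos = int(row["tss_position"])
            strand = (strand_by_gene or {}).get(row["gene_id"], ".")
            score = int(row["pileup_height"]) if pd.notna(row["pileup_height"]) else 0
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{row['gene_id']}\t{score}\t{strand}\n")
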