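"""CAGE-pileup transcription-start-site calling and 5'UTR assignment.

CAGE sequencing anchors capped 5' ends at single bases, so a per-base pileup
of 5'-end read counts locates transcription start sites (TSS).  For each
protein-coding gene the caller scans a strand-aware window starting 1000 nt
upstream of the earliest annotated transcript start and ending at the latest
coding start (in transcription order), and takes the position with the
greatest pileup as the TSS.  The 5'UTR is then assigned against the
transcript whose coding start lies the smallest number of bases downstream
of the called TSS.  Two exclusion rules apply: genes whose called TSS falls
downstream of (or exactly at) *any* transcript's coding start are excluded,
as are genes whose assigned 5'UTR exceeds 500 nt.

The window deliberately extends to the latest coding start rather than the
earliest: a pileup maximum that falls between two transcripts' coding starts
is exactly the situation the downstream-TSS exclusion rule exists for, and a
window ending at the earliest coding start could never observe it.

Pileup ties resolve to the position closest to the coding start (most
downstream on the gene strand), i.e. the shortest-UTR reading — deterministic
and conservative.  Counts are single-base 5'-end anchors; no smoothing is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ribolens.annotation import TranscriptModel

DEFAULT_WINDOW_UPSTREAM = 1000
DEFAULT_MAX_UTR5 = 500

STATUS_CALLED = "called"
STATUS_EXCLUDED_LONG = "excluded_long_utr"
STATUS_EXCLUDED_DOWNSTREAM = "excluded_downstream"
STATUS_NO_SIGNAL = "no_signal"
STATUSES = (
    STATUS_CALLED,
    STATUS_EXCLUDED_LONG,
    STATUS_EXCLUDED_DOWNSTREAM,
    STATUS_NO_SIGNAL,
)


@dataclass
class CageTrack:
    """Strand-specific per-base 5'-end read counts for one chromosome."""

    chrom: str
    strand: str
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for pos, c in self.counts.items():
            if c < 0 or c != int(c):
                raise ValueError(f"count at {pos} must be a non-negative integer")


@dataclass
class TssCall:
    """Outcome of TSS calling for one gene."""

    gene_id: str
    status: str
    tss_position: int | None = None
    chosen_transcript: str | None = None
    utr5_length: int | None = None
    pileup_height: int | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == STATUS_CALLED:
            assert self.utr5_length is not None and 0 < self.utr5_length <= DEFAULT_MAX_UTR5


def _tx_coord(pos: int, strand: str) -> int:
    # Transcription-order coordinate: increases 5'->3' on either strand.
    return pos if strand == "+" else -pos


def call_tss(
    transcripts: Sequence[TranscriptModel],
    track: CageTrack,
    window_upstream: int = DEFAULT_WINDOW_UPSTREAM,
) -> int | None:
    """Position of the greatest pileup in the gene's upstream scan window.

    The window runs, in transcription order, from ``window_upstream`` nt
    upstream of the earliest annotated transcript start to the latest coding
    start (exclusive).  Returns the genomic position of the maximal count, or
    ``None`` when the window contains no reads or is degenerate.
    """
    if not transcripts:
        raise ValueError("empty transcript list")
    strand = transcripts[0].strand
    gene_id = transcripts[0].gene_id
    if any(t.strand != strand or t.gene_id != gene_id for t in transcripts):
        raise ValueError("transcripts must share one gene and strand")
    if track.strand != strand:
        raise ValueError(
            f"track strand {track.strand!r} does not match gene strand {strand!r}"
        )

    if strand == "+":
        five_prime_starts = [t.transcript_start for t in transcripts]
        earliest_start = min(five_prime_starts)
        latest_coding = max(t.coding_start for t in transcripts)
        lo, hi = earliest_start - window_upstream, latest_coding  # [lo, hi)
        if hi <= lo:
            return None  # degenerate window

        def in_window(p: int) -> bool:
            return lo <= p < hi

    else:
        five_prime_starts = [t.transcript_end - 1 for t in transcripts]
        earliest_start = max(five_prime_starts)
        latest_coding = min(t.coding_start for t in transcripts)
        lo, hi = latest_coding, earliest_start + window_upstream  # (lo, hi]
        if lo >= hi:
            return None  # degenerate window

        def in_window(p: int) -> bool:
            return lo < p <= hi

    best_pos: int | None = None
    best_count = 0
    for pos, count in track.counts.items():
        if count <= 0 or not in_window(pos):
            continue
        if count > best_count:
            best_pos, best_count = pos, count
        elif count == best_count and best_pos is not None:
            # tie: most downstream on the gene strand (closest to coding start)
            if _tx_coord(pos, strand) > _tx_coord(best_pos, strand):
                best_pos = pos
    return best_pos


def assign_utr5(
    tss: int | None,
    transcripts: Sequence[TranscriptModel],
    max_utr5: int = DEFAULT_MAX_UTR5,
) -> TssCall:
    """Assign a 5'UTR to a called TSS, applying both exclusion rules.

    Among transcripts whose coding start is strictly downstream of the TSS,
    the one at minimal distance is chosen and that distance is the 5'UTR
    length.  A TSS downstream of (or at) *any* coding start excludes the
    gene; an assigned 5'UTR longer than ``max_utr5`` excludes it too.
    """
    if not transcripts:
        raise ValueError("empty transcript list")
    gene_id = transcripts[0].gene_id
    strand = transcripts[0].strand
    if tss is None:
        return TssCall(gene_id=gene_id, status=STATUS_NO_SIGNAL)

    sign = 1 if strand == "+" else -1
    distances = {t.transcript_id: sign * (t.coding_start - tss) for t in transcripts}
    if min(distances.values()) <= 0:
        # TSS at or downstream of some coding start: a 0-nt 5'UTR is
        # biologically degenerate, so distance 0 is excluded as well.
        return TssCall(
            gene_id=gene_id, status=STATUS_EXCLUDED_DOWNSTREAM, tss_position=tss
        )
    chosen = min(distances, key=lambda tid: (distances[tid], tid))
    utr5 = distances[chosen]
    status = STATUS_CALLED if utr5 <= max_utr5 else STATUS_EXCLUDED_LONG
    return TssCall(
        gene_id=gene_id,
        status=status,
        tss_position=tss,
        chosen_transcript=chosen,
        utr5_length=utr5,
    )


def call_all(
    gene_models: Mapping[str, Sequence[TranscriptModel]],
    tracks: Mapping[tuple[str, str], CageTrack],
    window_upstream: int = DEFAULT_WINDOW_UPSTREAM,
    max_utr5: int = DEFAULT_MAX_UTR5,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run TSS calling and 5'UTR assignment for every gene.

    ``tracks`` is keyed by (chrom, strand).  Returns the per-gene TssCall
    table and a status-count summary; the counts sum to the gene count.
    """
    rows = []
    summary = {status: 0 for status in STATUSES}
    for gene_id in sorted(gene_models):
        transcripts = gene_models[gene_id]
        key = (transcripts[0].chrom, transcripts[0].strand)
        track = tracks.get(key)
        if track is None:
            call = TssCall(gene_id=gene_id, status=STATUS_NO_SIGNAL)
        else:
            tss = call_tss(transcripts, track, window_upstream=window_upstream)
            call = assign_utr5(tss, transcripts, max_utr5=max_utr5)
            if call.status == STATUS_CALLED and track is not None:
                call.pileup_height = track.counts.get(call.tss_position, 0)
        summary[call.status] += 1
        rows.append(
            {
                "gene_id": call.gene_id,
                "status": call.status,
                "tss_position": call.tss_position,
                "chosen_transcript": call.chosen_transcript,
                "utr5_length": call.utr5_length,
                "pileup_height": call.pileup_height,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "status",
            "tss_position",
            "chosen_transcript",
            "utr5_length",
            "pileup_height",
        ],
    )
    return table, summary
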