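"""Synthetic translatome study generator with known ground truth.

Emulates the statistical structure the downstream analyses assume, so every
stage of the pipeline is testable without any deposited data:

* a gene universe with lognormally skewed CDS/UTR lengths and abundances;
* true log2 fold changes composed of a length-dependent trend (slope
  ``beta_len`` on centred log2 CDS length), an additive shift ``gamma_rp``
  for a ribosomal-protein-like set drawn from the shortest length tercile,
  and per-gene biological noise of sd ``sigma_noise``;
* observed differential tables with per-gene standard errors from a scaled
  inverse-chi distribution (``n_replicates`` degrees of freedom), normal
  test statistics, and BH-adjusted p-values;
* paired TRAP/total negative-binomial count matrices whose TRAP means are
  total means scaled by 2^(true log2fc);
* CAGE 5'-end pileups over single-exon gene models with Poisson signal at
  the true TSS and Poisson background, including planted genes that
  exercise both TSS-caller exclusion rules (decoy pileups downstream of a
  coding start; true 5'UTRs longer than 500 nt).

All randomness flows from one seed; each artifact uses its own named
substream (``default_rng([seed, stream])``) so regenerating any single
piece is stable regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ribolens.annotation import TranscriptModel
from ribolens.detables import DifferentialTable
from ribolens.genesets import GeneSetCollection, adjust_fdr
from ribolens.tss import CageTrack

_STREAMS = {"universe": 11, "de": 12, "counts": 13, "cage": 14, "fasta": 15}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic translatome experiment.

    Defaults describe a hippocampal-scale universe: ~12k expressed genes,
    CDS lengths lognormal(meanlog 7.2, sdlog 0.6) nt (median ~1.3 kb), an
    80-gene ribosomal-protein-like set from the shortest tercile shifted up
    by +0.3 log2 units, and a mild negative length trend of -0.05 log2
    units per log2 CDS unit.
    """

    n_genes: int = 12000
    cds_meanlog: float = 7.2
    cds_sdlog: float = 0.6
    utr5_meanlog: float = 4.8
    utr5_sdlog: float = 0.7
    utr3_meanlog: float = 6.2
    utr3_sdlog: float = 0.8
    rp_set_size: int = 80
    beta_len: float = -0.05
    gamma_rp: float = 0.3
    sigma_noise: float = 0.15
    se_scale: float = 0.08
    n_replicates: int = 4
    nb_dispersion: float = 0.05
    library_size: float = 3e6
    cage_signal_mean: float = 50.0
    cage_background: float = 0.05
    cage_window: int = 1000
    cage_n_genes: int = 300
    decoy_fraction: float = 0.10
    long_utr_fraction: float = 0.05
    n_go_like_sets: int = 150
    go_set_min: int = 20
    go_set_max: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rp_set_size >= self.n_genes:
            raise ValueError("rp_set_size must be below n_genes")
        for name in ("sigma_noise", "se_scale", "nb_dispersion", "cage_signal_mean", "cage_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def null(cls, **overrides) -> "SimulationConfig":
        """A no-effect configuration: flat length trend, no set shift, no
        biological spread — observed fold changes are pure measurement
        noise and p-values are uniform."""
        defaults = dict(beta_len=0.0, gamma_rp=0.0, sigma_noise=0.0)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class GroundTruth:
    """What the generator knows: true effects and, after CAGE generation,
    true TSS positions and 5'UTR lengths."""

    genes: pd.DataFrame
    tss: pd.DataFrame | None = None


def generate_universe(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GeneSetCollection, GroundTruth]:
    """Gene annotation table, gene-set collection and ground truth.

    The RP-like set is sampled from the shortest CDS tercile; GO-like sets
    of 20-50 random genes provide a null collection for set statistics and
    term networks.
    """
    rng = _rng(config.seed, "universe")
    n = config.n_genes
    gene_ids = np.array([f"G{i:06d}" for i in range(n)], dtype=object)
    tids = np.array([f"T{i:06d}.1" for i in range(n)], dtype=object)

    cds = np.maximum(90, (rng.lognormal(config.cds_meanlog, config.cds_sdlog, n) // 3).astype(int) * 3)
    utr5 = np.maximum(10, rng.lognormal(config.utr5_meanlog, config.utr5_sdlog, n).astype(int))
    utr3 = np.maximum(30, rng.lognormal(config.utr3_meanlog, config.utr3_sdlog, n).astype(int))
    transcript_length = utr5 + cds + utr3
    # genomic span: mature length inflated by an intronic expansion factor
    gene_length = (transcript_length * (1.0 + rng.lognormal(1.0, 1.0, n))).astype(int)
    gc = np.clip(rng.normal(0.47, 0.06, n), 0.25, 0.75)

    raw = rng.lognormal(1.0, 1.2, n)
    tpm = raw / raw.sum() * 1e6
    fpkm = tpm * np.exp(rng.normal(0.0, 0.05, n))

    log2_cds = np.log2(cds)
    centered = log2_cds - log2_cds.mean()
    tercile = np.quantile(cds, 1 / 3)
    short_pool = np.flatnonzero(cds <= tercile)
    if short_pool.size < config.rp_set_size:
        raise ValueError(
            f"rp_set_size={config.rp_set_size} exceeds the short length tercile "
            f"({short_pool.size} genes); lower it or raise n_genes"
        )
    rp_idx = rng.choice(short_pool, size=config.rp_set_size, replace=False)
    is_rp = np.zeros(n, dtype=bool)
    is_rp[rp_idx] = True

    true_lfc = (
        config.beta_len * centered
        + config.gamma_rp * is_rp
        + rng.normal(0.0, config.sigma_noise, n)
    )

    ann = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "principal_transcript": tids,
            "transcript_length": transcript_length,
            "cds_length": cds,
            "utr5_length": utr5.astype(float),
            "utr3_length": utr3,
            "gene_length": gene_length,
            "gc_cds": gc,
            "tpm": tpm,
            "fpkm": fpkm,
            "flag": "",
        }
    )

    sets = GeneSetCollection({"RP": set(gene_ids[is_rp])})
    sets.descriptions["RP"] = "ribosomal-protein-like set (short CDS tercile)"
    sizes = rng.integers(config.go_set_min, config.go_set_max + 1, config.n_go_like_sets)
    for i, size in enumerate(sizes):
        name = f"TERM{i:04d}"
        sets[name] = frozenset(rng.choice(gene_ids, size=size, replace=False))
        sets.descriptions[name] = "random functional term"

    truth = GroundTruth(
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "cds_length": cds,
                "true_log2fc": true_lfc,
                "is_rp": is_rp,
            }
        )
    )
    return ann, sets, truth


def generate_de_table(
    truth: GroundTruth,
    config: SimulationConfig,
    contrast_name: str = "trap_vs_total",
) -> DifferentialTable:
    """Observed differential table: true log2fc plus se-scaled noise.

    Per-gene standard errors follow a scaled inverse-chi law with
    ``n_replicates`` degrees of freedom (se = se_scale * sqrt(df / chi2)),
    the test statistic is log2fc/se with a normal reference, and adjusted
    p-values are Benjamini-Hochberg.
    """
    rng = _rng(config.seed, "de")
    genes = truth.genes
    n = len(genes)
    df_ = max(1, config.n_replicates)
    chi2 = rng.chisquare(df_, n)
    se = config.se_scale * np.sqrt(df_ / chi2)
    observed = genes["true_log2fc"].to_numpy() + se * rng.normal(0.0, 1.0, n)
    stat = np.divide(observed, se, out=np.zeros(n), where=se > 0)
    pvalue = 2 * stats.norm.sf(np.abs(stat))
    if config.se_scale == 0:
        observed = genes["true_log2fc"].to_numpy().copy()
        pvalue = np.ones(n)
        stat = np.zeros(n)
    padj = adjust_fdr(pvalue)
    table = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "log2fc": observed,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
        }
    )
    return DifferentialTable(name=contrast_name, df=table)


def generate_counts(
    ann: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]]]:
    """Paired TRAP/total negative-binomial count matrices.

    Total means scale with TPM and library size; TRAP means multiply by
    2^(true log2fc).  ``nb_dispersion`` of zero degenerates to Poisson.
    Returns (trap, total, pairs) with pairs as (trap_sample, total_sample).
    """
    rng = _rng(config.seed, "counts")
    mu_total = ann["tpm"].to_numpy() / 1e6 * config.library_size
    mu_trap = mu_total * np.exp2(truth.genes["true_log2fc"].to_numpy())
    index = pd.Index(ann["gene_id"], name="gene_id")

    def _draw(mu: np.ndarray) -> np.ndarray:
        if config.nb_dispersion == 0:
            return rng.poisson(mu)
        k = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape=k, scale=np.maximum(mu, 1e-300) / k)
        out = rng.poisson(lam)
        out[mu == 0] = 0
        return out

    trap_cols, total_cols, pairs = {}, {}, []
    for rep in range(1, config.n_replicates + 1):
        t_name, n_name = f"trap_{rep}", f"total_{rep}"
        trap_cols[t_name] = _draw(mu_trap)
        total_cols[n_name] = _draw(mu_total)
        pairs.append((t_name, n_name))
    return (
        pd.DataFrame(trap_cols, index=index),
        pd.DataFrame(total_cols, index=index),
        pairs,
    )


def generate_cage(
    ann: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[dict[str, list[TranscriptModel]], dict[tuple[str, str], CageTrack], pd.DataFrame]:
    """Single-exon gene models plus CAGE pileups with known true TSS.

    The first ``cage_n_genes`` genes of the universe are laid out along one
    chromosome with alternating strands.  Most genes get one transcript
    whose annotated start sits within ±30 nt of the true TSS and a Poisson
    signal spike (mean ``cage_signal_mean``) at the true TSS over Poisson
    background (rate ``cage_background`` per base in the scan window).

    Planted exceptions exercise the exclusion rules: ``decoy_fraction`` of
    genes carry a second short-5'UTR transcript and a stronger decoy spike
    downstream of its coding start (expected status excluded_downstream);
    ``long_utr_fraction`` get a true 5'UTR of 550-900 nt (expected status
    excluded_long_utr).

    Returns (gene models by gene, tracks by (chrom, strand), truth table
    with per-gene true TSS, true 5'UTR length and expected status).
    """
    rng = _rng(config.seed, "cage")
    n = min(config.cage_n_genes, len(ann))
    sub = ann.iloc[:n]
    chrom = "chrS"
    window = config.cage_window

    n_decoy = int(round(config.decoy_fraction * n))
    n_long = int(round(config.long_utr_fraction * n))
    roles = np.array(["normal"] * n, dtype=object)
    special = rng.choice(n, size=n_decoy + n_long, replace=False)
    roles[special[:n_decoy]] = "decoy"
    roles[special[n_decoy : n_decoy + n_long]] = "long_utr"

    gene_models: dict[str, list[TranscriptModel]] = {}
    plus_counts: dict[int, int] = {}
    minus_counts: dict[int, int] = {}
    truth_rows = []
    cursor = 2 * window  # leave room for the first upstream window

    for i in range(n):
        row = sub.iloc[i]
        gene_id = row["gene_id"]
        tid = row["principal_transcript"]
        strand = "+" if i % 2 == 0 else "-"
        role = roles[i]
        cds_len = int(row["cds_length"])
        utr3 = int(row["utr3_length"])
        if role == "long_utr":
            utr5_true = int(rng.integers(551, 901))
        else:
            utr5_true = int(rng.integers(20, 451))
        jitter = int(rng.integers(-30, 31))
        counts = plus_counts if strand == "+" else minus_counts
        span = utr5_true + cds_len + utr3 + abs(jitter) + 2 * window

        if strand == "+":
            tss_true = cursor + window
            ann_start = tss_true + jitter
            coding_start = tss_true + utr5_true
            end = coding_start + cds_len + utr3
            transcripts = [
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    transcript_start=ann_start,
                    transcript_end=end,
                    coding_start=coding_start,
                    exon_intervals=[(ann_start, end)],
                    cds_length=cds_len,
                    utr3_length=utr3,
                )
            ]
            scan_lo, scan_hi = ann_start - window, coding_start
            decoy_pos = None
            if role == "decoy":
                # second transcript with a short 5'UTR; decoy spike between
                # its coding start and the main one
                c0 = tss_true + 50
                if c0 < coding_start - 10:
                    transcripts.append(
                        TranscriptModel(
                            transcript_id=tid.replace(".1", ".2"),
                            gene_id=gene_id,
                            chrom=chrom,
                            strand=strand,
                            transcript_start=ann_start,
                            transcript_end=end,
                            coding_start=c0,
                            exon_intervals=[(ann_start, end)],
                            cds_length=cds_len,
                            utr3_length=utr3,
                        )
                    )
                    decoy_pos = int(rng.integers(c0 + 1, coding_start))
                    scan_hi = coding_start
                else:
                    role = "normal"
        else:
            # mirrored layout: 5' end on the right
            end_3p = cursor + window  # genomic left edge (3' end of the gene)
            coding_start = end_3p + utr3 + cds_len - 1  # first CDS base, transcription order
            tss_true = coding_start + utr5_true
            ann_5p = tss_true + jitter
            end = ann_5p + 1
            start = end_3p
            transcripts = [
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    transcript_start=start,
                    transcript_end=end,
                    coding_start=coding_start,
                    exon_intervals=[(start, end)],
                    cds_length=cds_len,
                    utr3_length=utr3,
                )
            ]
            scan_lo, scan_hi = coding_start + 1, (end - 1) + window  # inclusive range
            decoy_pos = None
            if role == "decoy":
                c0 = tss_true - 50
                if c0 > coding_start + 10:
                    transcripts.append(
                        TranscriptModel(
                            transcript_id=tid.replace(".1", ".2"),
                            gene_id=gene_id,
                            chrom=chrom,
                            strand=strand,
                            transcript_start=start,
                            transcript_end=end,
                            coding_start=c0,
                            exon_intervals=[(start, end)],
                            cds_length=cds_len,
                            utr3_length=utr3,
                        )
                    )
                    decoy_pos = int(rng.integers(coding_start + 1, c0))
                else:
                    role = "normal"

        # signal at the true TSS
        signal = max(1, int(rng.poisson(config.cage_signal_mean)))
        counts[tss_true] = counts.get(tss_true, 0) + signal
        if decoy_pos is not None:
            counts[decoy_pos] = counts.get(decoy_pos, 0) + 2 * signal
        # background across the scan window
        if config.cage_background > 0:
            lo, hi = int(scan_lo), int(scan_hi)
            bg = rng.poisson(config.cage_background, max(0, hi - lo))
            for off in np.flatnonzero(bg):
                pos = lo + int(off)
                counts[pos] = counts.get(pos, 0) + int(bg[off])

        gene_models[gene_id] = transcripts
        expected = {
            "normal": "called",
            "decoy": "excluded_downstream",
            "long_utr": "excluded_long_utr",
        }[role]
        truth_rows.append(
            {
                "gene_id": gene_id,
                "strand": strand,
                "true_tss": tss_true,
                "true_utr5": utr5_true,
                "expected_status": expected,
            }
        )
        cursor += span + window

    tracks = {
        (chrom, "+"): CageTrack(chrom=chrom, strand="+", counts=plus_counts),
        (chrom, "-"): CageTrack(chrom=chrom, strand="-", counts=minus_counts),
    }
    tss_truth = pd.DataFrame(truth_rows)
    return gene_models, tracks, tss_truth


def generate_cds_sequences(
    ann: pd.DataFrame, config: SimulationConfig
) -> dict[str, str]:
    """Random CDS nucleotide strings matching each gene's length and GC."""
    rng = _rng(config.seed, "fasta")
    seqs = {}
    bases = np.array(list("GCAT"))
    for tid, length, gc in zip(ann["principal_transcript"], ann["cds_length"], ann["gc_cds"]):
        p = np.array([gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2])
        seqs[tid] = "".join(rng.choice(bases, size=int(length), p=p))
    return seqs
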