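"""CDS-length-dependent translation-bias analyses.

A translating-mRNA population enriched in ribosomes shifts the balance of
translation between short and long transcripts.  This module quantifies
that shift three ways:

* length bins (<1 kb, 1-2 kb, 2-4 kb, >4 kb of CDS by default) whose
  fold-change distributions are compared with two-sample KS tests;
* the top-N most up- and downregulated genes, whose log2(CDS length)
  distributions are compared against the whole detected population (and
  against each other) with two-sample z tests;
* a length-ranked gene-set analysis, where genes are ranked by CDS length
  (shortest-first and longest-first) and small GO terms (20-50 genes) are
  tested with the mean-rank statistic;

plus the 2x2 classification of a gene set by CDS-length and gene-length
thresholds (log2 CDS = 11, log2 gene span = 16) used to ask whether coding
or genomic length drives an expression change.

Bins are half-open [lo, hi), so a 1000-nt CDS falls in the 1-2 kb bin.
Lengths enter z tests on the log2 scale by default.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ribolens.genesets import (
    GeneSetCollection,
    RankedList,
    attach_fdr,
    gsa_mean_rank,
    results_to_frame,
    two_sample_z,
)

logger = logging.getLogger(__name__)

DEFAULT_EDGES = (0.0, 1000.0, 2000.0, 4000.0, math.inf)


def _bin_labels(edges: Sequence[float]) -> list[str]:
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == 0:
            labels.append(f"<{hi:g}")
        elif math.isinf(hi):
            labels.append(f">={lo:g}")
        else:
            labels.append(f"{lo:g}-{hi:g}")
    return labels


def bin_by_cds_length(
    lengths: pd.Series, edges: Sequence[float] = DEFAULT_EDGES
) -> pd.Series:
    """Assign each gene to a half-open [lo, hi) CDS-length bin.

    Genes with missing or non-positive length are excluded (logged count).
    """
    edges = tuple(edges)
    if list(edges) != sorted(edges) or len(edges) < 2:
        raise ValueError("edges must be increasing with >= 2 entries")
    values = pd.to_numeric(lengths, errors="coerce")
    ok = values.notna() & (values > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("bin_by_cds_length: excluded %d genes without usable length", n_dropped)
    values = values[ok]
    labels = _bin_labels(edges)
    idx = np.digitize(values.to_numpy(float), edges[1:-1], right=False)
    return pd.Series(
        pd.Categorical([labels[i] for i in idx], categories=labels),
        index=values.index,
        name="length_bin",
    )


def ks_two_sample(
    x: Sequence[float], y: Sequence[float], min_n: int = 2
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: d = sup|ECDF_x - ECDF_y|.

    Two-sided p from the asymptotic Kolmogorov distribution.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < min_n or y.size < min_n:
        raise ValueError(f"each sample needs >= {min_n} values")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def binned_report(
    de_df: pd.DataFrame,
    ann: pd.DataFrame,
    edges: Sequence[float] = DEFAULT_EDGES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin fold-change summaries plus pairwise KS tests between bins."""
    merged = de_df.merge(ann[["gene_id", "cds_length"]], on="gene_id")
    bins = bin_by_cds_length(merged.set_index("gene_id")["cds_length"], edges)
    merged = merged.set_index("gene_id").loc[bins.index]
    merged["length_bin"] = bins
    summary = (
        merged.groupby("length_bin", observed=False)["log2fc"]
        .agg(n="size", mean="mean", median="median", sd="std")
        .reset_index()
    )
    labels = list(bins.cat.categories)
    ks_rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            xa = merged.loc[merged["length_bin"] == a, "log2fc"]
            xb = merged.loc[merged["length_bin"] == b, "log2fc"]
            if len(xa) >= 2 and len(xb) >= 2:
                d, p = ks_two_sample(xa, xb)
                ks_rows.append({"bin_a": a, "bin_b": b, "d": d, "p": p})
    return summary, pd.DataFrame(ks_rows)


def top_n_length_comparison(
    de_df: pd.DataFrame,
    ann: pd.DataFrame,
    n: int = 500,
    rank_by: str = "log2fc",
    log_scale: bool = True,
) -> pd.DataFrame:
    """z tests of (log2) CDS length for the top-N up/down regulated genes.

    ``rank_by='log2fc'`` takes the n largest and n smallest fold changes;
    ``rank_by='pvalue_signed'`` takes the n smallest nominal p-values within
    each fold-change sign.  Compares up-vs-all, down-vs-all and up-vs-down,
    where "all" is the whole detected universe (top/bottom genes included).
    """
    merged = de_df.merge(ann[["gene_id", "cds_length"]], on="gene_id")
    merged = merged[merged["cds_length"] > 0]
    if len(merged) < 2 * n:
        raise ValueError(
            f"universe of {len(merged)} genes cannot supply 2*n={2 * n}; lower n"
        )
    if rank_by == "log2fc":
        ordered = merged.sort_values(["log2fc", "gene_id"], ascending=[False, True])
        up = ordered.head(n)
        down = ordered.tail(n)
    elif rank_by == "pvalue_signed":
        pos = merged[merged["log2fc"] > 0].sort_values(["pvalue", "gene_id"])
        neg = merged[merged["log2fc"] < 0].sort_values(["pvalue", "gene_id"])
        if len(pos) < n or len(neg) < n:
            raise ValueError(
                f"sign pools of {len(pos)} up / {len(neg)} down cannot supply n={n}"
            )
        up, down = pos.head(n), neg.head(n)
    else:
        raise ValueError(f"rank_by must be log2fc or pvalue_signed, got {rank_by!r}")

    def _vals(df: pd.DataFrame) -> np.ndarray:
        v = df["cds_length"].to_numpy(float)
        return np.log2(v) if log_scale else v

    groups = {"up": _vals(up), "down": _vals(down), "all": _vals(merged)}
    rows = []
    for name_a, name_b in [("up", "all"), ("down", "all"), ("up", "down")]:
        z, p = two_sample_z(groups[name_a], groups[name_b])
        rows.append(
            {
                "comparison": f"{name_a}_vs_{name_b}",
                "z": z,
                "p": p,
                "mean_a": float(groups[name_a].mean()),
                "mean_b": float(groups[name_b].mean()),
                "n_a": groups[name_a].size,
                "n_b": groups[name_b].size,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["rank_by"] = rank_by
    out.attrs["reference"] = "all_detected_including_topn"
    return out


def length_ranked_gsa(
    ann: pd.DataFrame,
    sets: GeneSetCollection,
    min_size: int = 20,
    max_size: int = 50,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    top: int = 7,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Mean-rank GSA on CDS-length-ranked gene lists, in both orientations.

    Builds two ranked lists — top rank to the shortest gene and top rank to
    the longest gene — filters the collection to sets with ``min_size`` to
    ``max_size`` members in the universe, and runs the mean-rank statistic
    per set.  Returns, per orientation, the full result table and the top
    ``top`` terms sorted by p-value then enrichment magnitude.
    """
    lengths = ann.set_index("gene_id")["cds_length"]
    lengths = lengths[lengths > 0]
    filtered = sets.filter_by_size(lengths.index, min_size=min_size, max_size=max_size)
    if not filtered:
        logger.warning("no gene sets within size bounds [%d, %d]", min_size, max_size)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for orientation, label in [("ascending", "shortest_first"), ("descending", "longest_first")]:
        ranked = RankedList.from_metric(lengths, orientation=orientation)
        results = [
            gsa_mean_rank(ranked, filtered[name], n_perm=n_perm, seed=rng, set_name=name)
            for name in sorted(filtered)
        ]
        attach_fdr(results)
        frame = results_to_frame(results)
        if len(frame):
            expected = (len(ranked) + 1) / 2
            frame["enrichment"] = (expected - frame["observed"]) / expected
            ordered = frame.reindex(
                frame.assign(absenr=frame["enrichment"].abs())
                .sort_values(["p_nominal", "absenr"], ascending=[True, False])
                .index
            )
            top_frame = ordered.head(top).reset_index(drop=True)
        else:
            top_frame = frame
        out[label] = {"all": frame, "top": top_frame}
    return out


def length_group_table(
    ann: pd.DataFrame,
    gene_set: Iterable[str],
    cds_threshold_log2: float = 11.0,
    gene_threshold_log2: float = 16.0,
) -> pd.DataFrame:
    """2x2 counts of a gene set by CDS-length and gene-length thresholds.

    Cells split at CDS length >= 2^11 nt and gene span >= 2^16 nt (>= on
    the high side).  Counts sum to |set ∩ annotated universe|.
    """
    sub = ann[ann["gene_id"].isin(set(gene_set))]
    sub = sub[(sub["cds_length"] > 0) & (sub["gene_length"] > 0)]
    cds_high = sub["cds_length"] >= 2.0**cds_threshold_log2
    gene_high = sub["gene_length"] >= 2.0**gene_threshold_log2
    table = pd.DataFrame(
        {
            "gene_high": [
                int((cds_high & gene_high).sum()),
                int((~cds_high & gene_high).sum()),
            ],
            "gene_low": [
                int((cds_high & ~gene_high).sum()),
                int((~cds_high & ~gene_high).sum()),
            ],
        },
        index=pd.Index(["cds_high", "cds_low"], name="cds_group"),
    )
    return table
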