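"""End-to-end orchestration: one config in, a report bundle out.

The demo mode generates a synthetic study and runs every analysis stage —
gene table, TSS calls, ribosomal-protein set statistics, length-bias report,
term z-scores with network clustering — writing TSVs plus a run manifest
(package version, seed, every threshold used).  Runs are idempotent under a
fixed seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

import ribolens
from ribolens import io
from ribolens.annotation import filter_expressed
from ribolens.genesets import (
    RankedList,
    attach_fdr,
    gsa_mean_rank,
    results_to_frame,
    size_matched_reference,
    two_sample_z,
)
from ribolens.gonetwork import (
    build_term_network,
    cluster_terms,
    clusters_to_frame,
    edges_to_frame,
    prune_redundant_terms,
    term_zscore_table,
    zscore_population_test,
)
from ribolens.lengthbias import binned_report, length_ranked_gsa, top_n_length_comparison
from ribolens.simulate import (
    SimulationConfig,
    generate_cage,
    generate_de_table,
    generate_universe,
)
from ribolens.tss import call_all

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative run description; every threshold is echoed to the manifest."""

    outdir: str = "ribolens_run"
    seed: int = 0
    n_perm: int = 1000
    alpha_adj: float = 0.1
    alpha_nominal: float = 0.05
    fpkm_threshold: float = 2.0
    top_n: int = 500
    min_set: int = 20
    max_set: int = 50
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha_adj", "alpha_nominal"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic-study pipeline; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "ribolens",
        "version": ribolens.__version__,
        "seed": config.seed,
        "thresholds": {
            "alpha_adj": config.alpha_adj,
            "alpha_nominal": config.alpha_nominal,
            "fpkm_threshold": config.fpkm_threshold,
            "n_perm": config.n_perm,
            "top_n": config.top_n,
            "min_set": config.min_set,
            "max_set": config.max_set,
        },
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                **info,
            }
            logger.info("stage %s done (%.2fs)", name, time.perf_counter() - t0)

        return done

    sim = config.sim_config()

    done = stage("simulate")
    ann, sets, truth = generate_universe(sim)
    de = generate_de_table(truth, sim)
    done(n_genes=len(ann), n_sets=len(sets))

    done = stage("annotate")
    expressed = filter_expressed(ann, threshold=config.fpkm_threshold)
    io.write_gene_table(ann, outdir / "gene_table.tsv")
    de.df.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
    done(n_expressed=len(expressed))

    done = stage("call_tss")
    gene_models, tracks, tss_truth = generate_cage(ann, truth, sim)
    calls, summary = call_all(gene_models, tracks)
    calls.to_csv(outdir / "tss_calls.tsv", sep="\t", index=False)
    done(**summary)

    done = stage("set_stats")
    rng = np.random.default_rng([config.seed, 101])
    ranked = RankedList.from_metric(
        de.df.set_index("gene_id")["log2fc"], orientation="descending"
    )
    results = [
        gsa_mean_rank(ranked, sets[name], n_perm=config.n_perm, seed=rng, set_name=name)
        for name in sorted(sets)
    ]
    attach_fdr(results)
    set_frame = results_to_frame(results)
    lfc = de.df.set_index("gene_id")["log2fc"]
    rp = sets["RP"]
    z_all, p_all = two_sample_z(lfc.reindex(sorted(rp)), lfc)
    pooled, _ = size_matched_reference(lfc, rp, n_draws=200, seed=rng)
    z_matched, p_matched = two_sample_z(lfc.reindex(sorted(rp)), pooled)
    set_frame.to_csv(outdir / "set_stats.tsv", sep="\t", index=False)
    done(
        rp_z_vs_all=round(z_all, 4),
        rp_p_vs_all=p_all,
        rp_z_vs_size_matched=round(z_matched, 4),
        rp_p_vs_size_matched=p_matched,
        reference_modes=["all_detected", "size_matched_random"],
    )

    done = stage("length_bias")
    bins, ks = binned_report(de.df, expressed)
    topn = top_n_length_comparison(de.df, expressed, n=config.top_n)
    gsa = length_ranked_gsa(
        expressed,
        sets,
        min_size=config.min_set,
        max_size=config.max_set,
        n_perm=config.n_perm,
        seed=np.random.default_rng([config.seed, 102]),
    )
    bins.to_csv(outdir / "length_bins.tsv", sep="\t", index=False)
    ks.to_csv(outdir / "length_ks.tsv", sep="\t", index=False)
    topn.to_csv(outdir / "length_topn.tsv", sep="\t", index=False)
    for label, frames in gsa.items():
        frames["top"].to_csv(outdir / f"length_gsa_{label}.tsv", sep="\t", index=False)
    done(
        topn_z_up_vs_all=round(float(topn.loc[0, "z"]), 4),
        topn_z_down_vs_all=round(float(topn.loc[1, "z"]), 4),
    )

    done = stage("go_network")
    zt = term_zscore_table(sets, de, classification="sign")
    zt.to_csv(outdir / "term_zscores.tsv", sep="\t", index=False)
    pruned, removed = prune_redundant_terms(sets)
    graph = build_term_network(pruned, dict(zip(zt["term_id"], zt["z"])))
    labels = cluster_terms(graph)
    edges_to_frame(graph).to_csv(outdir / "term_edges.tsv", sep="\t", index=False)
    clusters_to_frame(labels).to_csv(outdir / "term_clusters.tsv", sep="\t", index=False)
    done(n_terms=len(pruned), n_removed=len(removed), n_clusters=len(set(labels.values())))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
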