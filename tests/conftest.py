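import numpy as np
import pandas as pd
import pytest

from ribolens.annotation import TranscriptModel
from ribolens.detables import DifferentialTable
from ribolens.simulate import SimulationConfig, generate_de_table, generate_universe


@pytest.fixture(scope="session")
def small_study():
    """A small default-effect synthetic study shared across tests."""
    config = SimulationConfig(n_genes=2000, cage_n_genes=120, seed=7)
    ann, sets, truth = generate_universe(config)
    de = generate_de_table(truth, config)
    return config, ann, sets, truth, de


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_de(genes, log2fc, pvalue=None, padj=None, name="test"):
    n = len(genes)
    df = pd.DataFrame(
        {
            "gene_id": list(genes),
            "log2fc": list(log2fc),
            "pvalue": list(pvalue) if pvalue is not None else [0.5] * n,
        }
    )
    if padj is not None:
        df["padj"] = list(padj)
    return DifferentialTable(name=name, df=df)


def make_transcript(
    tid="T1",
    gene="G1",
    strand="+",
    start=1000,
    end=2000,
    coding_start=1060,
    cds_length=600,
    utr3_length=100,
    chrom="chr1",
):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene,
        chrom=chrom,
        strand=strand,
        transcript_start=start,
        transcript_end=end,
        coding_start=coding_start,
        exon_intervals=[(start, end)],
        cds_length=cds_length,
        utr3_length=utr3_length,
    )
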