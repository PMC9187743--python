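"""Operations on differential-expression and proteome result tables.

Tables arrive from upstream model fits (DESeq2 for TRAP/RNA-seq contrasts,
moderated effect sizes for proteomics) as per-gene rows of log2 fold change,
test statistic and nominal/adjusted p-values; nothing is refit here.  The
module covers the cross-table bookkeeping those analyses need: significance
sets at an adjusted-p cutoff, genes moving the same direction in every
matched pair, Pearson correlation between contrasts, TRAP/total count
ratios, and hypergeometric overlap tests.

Conventions: all significance thresholds are strict inequalities (padj <
0.1, p < 0.05); a missing adjusted p (DESeq2 independent filtering) counts
as non-significant; overlap tests are run against a detection-conditioned
universe (genes detected in both contrasts), not the genome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["gene_id", "log2fc", "pvalue"]
OPTIONAL_COLUMNS = ["stat", "padj"]


@dataclass
class DifferentialTable:
    """One contrast's per-gene differential results."""

    name: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"{self.name}: missing required columns {missing}")
        dup = self.df["gene_id"][self.df["gene_id"].duplicated()]
        if len(dup):
            raise ValueError(
                f"{self.name}: duplicated gene_id values: {sorted(set(dup))[:10]}"
            )
        pv = self.df["pvalue"].dropna()
        if ((pv < 0) | (pv > 1)).any():
            raise ValueError(f"{self.name}: p-values outside [0, 1]")

    @property
    def genes(self) -> set[str]:
        return set(self.df["gene_id"])

    def indexed(self) -> pd.DataFrame:
        return self.df.set_index("gene_id")


def read_de_table(path, name: str | None = None) -> DifferentialTable:
    """Read a TSV differential table (gene_id, log2fc[, stat], pvalue[, padj]).

    Rows whose numeric fields fail to parse are dropped with a logged count;
    a missing ``padj`` column is allowed (treated as all-missing), a missing
    required column is a format error naming the column.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df = raw.copy()
    for col in ["log2fc", "pvalue"] + [c for c in OPTIONAL_COLUMNS if c in df.columns]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = df["log2fc"].notna() & df["pvalue"].notna() & df["gene_id"].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d rows with unparseable values", path, n_dropped)
    df = df.loc[ok].reset_index(drop=True)
    return DifferentialTable(name=name or str(path), df=df)


def trap_over_total(
    trap: pd.DataFrame,
    total: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Per-gene TRAP/total count ratio for each matched sample pair.

    ``pairs`` lists (trap_sample, total_sample) column names.  A pair with a
    zero total count yields a missing ratio for that gene/pair.
    """
    for trap_col, total_col in pairs:
        if trap_col not in trap.columns:
            raise ValueError(f"unmatched TRAP sample {trap_col!r}")
        if total_col not in total.columns:
            raise ValueError(f"unmatched total sample {total_col!r}")
    if not trap.index.equals(total.index):
        trap, total = trap.align(total, join="inner", axis=0)
    out = {}
    for trap_col, total_col in pairs:
        denom = total[total_col].astype(float).replace(0.0, np.nan)
        out[f"{trap_col}/{total_col}"] = trap[trap_col].astype(float) / denom
    return pd.DataFrame(out, index=trap.index)


def significant_set(
    table: DifferentialTable,
    alpha_adj: float = 0.1,
    direction: str = "both",
) -> set[str]:
    """Genes with adjusted p strictly below ``alpha_adj`` in the given direction.

    ``direction`` is 'up' (log2fc > 0), 'down' (log2fc < 0) or 'both'.
    Missing adjusted p-values are non-significant.
    """
    if direction not in ("up", "down", "both"):
        raise ValueError(f"direction must be up/down/both, got {direction!r}")
    if "padj" not in table.df.columns:
        raise ValueError(f"{table.name}: no padj column")
    df = table.df
    sig = df["padj"].notna() & (df["padj"] < alpha_adj)
    if direction == "up":
        sig &= df["log2fc"] > 0
    elif direction == "down":
        sig &= df["log2fc"] < 0
    return set(df.loc[sig, "gene_id"])


def consistent_direction_genes(
    tables: Sequence[DifferentialTable],
) -> tuple[set[str], set[str]]:
    """Genes up (resp. down) in every table of a matched family.

    A gene absent from any table is excluded from both sets; the returned
    sets are disjoint by construction.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    shared = set.intersection(*(t.genes for t in tables))
    signs = pd.DataFrame(
        {i: t.indexed()["log2fc"].reindex(sorted(shared)) for i, t in enumerate(tables)}
    )
    up = set(signs.index[(signs > 0).all(axis=1)])
    down = set(signs.index[(signs < 0).all(axis=1)])
    return up, down


def correlate_contrasts(
    table_a: DifferentialTable,
    table_b: DifferentialTable,
    genes: Iterable[str] | None = None,
) -> tuple[float, float]:
    """Pearson correlation of log2 fold changes between two contrasts.

    Restricted to ``genes`` when given, otherwise to all shared genes.
    Returns (r, two-sided p); zero variance in either vector yields
    (nan, nan) with a warning.
    """
    shared = table_a.genes & table_b.genes
    if genes is not None:
        shared &= set(genes)
    shared = sorted(shared)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    x = table_a.indexed()["log2fc"].reindex(shared).to_numpy(float)
    y = table_b.indexed()["log2fc"].reindex(shared).to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in a contrast; correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def overlap_test(
    set_a: Iterable[str], set_b: Iterable[str], universe_size: int
) -> tuple[int, float]:
    """Upper-tail hypergeometric test for the overlap of two gene sets.

    Models |A ∩ B| as hypergeometric(universe_size, |A|, |B|) and returns
    (observed overlap, P[X >= observed]).
    """
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than universe")
    k = len(a & b)
    if k > min(len(a), len(b)):  # pragma: no cover - impossible by construction
        raise ValueError("overlap exceeds set sizes")
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return k, p
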