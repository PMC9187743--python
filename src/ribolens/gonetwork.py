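"""GO-term sign-imbalance z scores and shared-gene network clustering.

For a functional term with ``n_total`` detected member genes, of which
``n_up`` move up and ``n_down`` move down in a contrast, the sign-imbalance
score is

    z = (n_up - n_down) / sqrt(n_total)

— the scaled excess of upregulated over downregulated members, bounded by
±sqrt(n_total).  A family of terms of interest (e.g. those downregulated by
a stimulus) is compared against the score distribution of *all* detected
terms with a two-sample z test.

For network views of term relationships, near-duplicate terms (sharing 90%
of genes with a larger term) are pruned, terms become nodes, edges carry
the shared-gene count as weight, and communities are found with the
Girvan-Newman edge-betweenness algorithm, cutting at maximal modularity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from ribolens.detables import DifferentialTable
from ribolens.genesets import GeneSetCollection, two_sample_z


@dataclass
class TermZScore:
    """Sign-imbalance score of one term in one contrast."""

    term_id: str
    n_up: int
    n_down: int
    n_total: int
    z: float

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_total:
            raise ValueError("n_up + n_down cannot exceed n_total")


def term_zscore(
    term_genes: Iterable[str],
    de: DifferentialTable,
    classification: str = "sign",
    alpha: float = 0.1,
    term_id: str = "",
) -> TermZScore:
    """Eq.-style sign-imbalance z for one term against one contrast.

    ``classification='sign'`` counts every detected term gene by the sign
    of its log2 fold change (exact zeros count in neither group);
    ``'significance'`` counts only genes with adjusted p < ``alpha``.  A
    term with no detected genes yields z = NaN.
    """
    if classification not in ("sign", "significance"):
        raise ValueError(f"classification must be sign/significance: {classification!r}")
    idx = de.indexed()
    members = sorted(set(term_genes) & set(idx.index))
    n_total = len(members)
    if n_total == 0:
        return TermZScore(term_id=term_id, n_up=0, n_down=0, n_total=0, z=math.nan)
    sub = idx.loc[members]
    lfc = sub["log2fc"]
    if classification == "sign":
        up = lfc > 0
        down = lfc < 0
    else:
        if "padj" not in sub.columns:
            raise ValueError("significance classification needs a padj column")
        sig = sub["padj"].notna() & (sub["padj"] < alpha)
        up = sig & (lfc > 0)
        down = sig & (lfc < 0)
    n_up, n_down = int(up.sum()), int(down.sum())
    z = (n_up - n_down) / math.sqrt(n_total)
    return TermZScore(term_id=term_id, n_up=n_up, n_down=n_down, n_total=n_total, z=z)


def term_zscore_table(
    sets: GeneSetCollection,
    de: DifferentialTable,
    classification: str = "sign",
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Sign-imbalance z for every term of a collection (NaN terms dropped)."""
    rows = []
    for name in sorted(sets):
        t = term_zscore(sets[name], de, classification=classification, alpha=alpha, term_id=name)
        if not math.isnan(t.z):
            rows.append(
                {
                    "term_id": t.term_id,
                    "n_up": t.n_up,
                    "n_down": t.n_down,
                    "n_total": t.n_total,
                    "z": t.z,
                }
            )
    return pd.DataFrame(rows, columns=["term_id", "n_up", "n_down", "n_total", "z"])


def zscore_population_test(
    target_terms: Sequence[TermZScore | float],
    all_terms: Sequence[TermZScore | float],
) -> tuple[float, float]:
    """Two-sample z test of a target term family against all detected terms."""

    def _vals(terms) -> list[float]:
        return [t.z if isinstance(t, TermZScore) else float(t) for t in terms]

    return two_sample_z(_vals(target_terms), _vals(all_terms))


def prune_redundant_terms(
    sets: GeneSetCollection, overlap_fraction: float = 0.9
) -> tuple[GeneSetCollection, list[tuple[str, str, float]]]:
    """Drop near-duplicate terms sharing ``overlap_fraction`` of their genes.

    The overlap fraction of a pair is |A ∩ B| / min(|A|, |B|) — "shares 90%
    of its genes" read against the smaller set.  Pairs are scanned by
    descending overlap then term id; for each violating pair still alive,
    the smaller term (tie: lexicographically later) is removed.  Returns the
    surviving collection and a removal log of (removed, kept, fraction).
    """
    names = sorted(sets)
    pairs = []
    for a, b in itertools.combinations(names, 2):
        inter = len(sets[a] & sets[b])
        denom = min(len(sets[a]), len(sets[b]))
        if denom == 0:
            continue
        frac = inter / denom
        if frac >= overlap_fraction:
            pairs.append((frac, a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    alive = set(names)
    removed_log: list[tuple[str, str, float]] = []
    for frac, a, b in pairs:
        if a not in alive or b not in alive:
            continue
        if len(sets[a]) < len(sets[b]):
            drop, keep = a, b
        elif len(sets[b]) < len(sets[a]):
            drop, keep = b, a
        else:  # equal size: drop the lexicographically later term
            drop, keep = max(a, b), min(a, b)
        alive.discard(drop)
        removed_log.append((drop, keep, frac))
    out = GeneSetCollection({n: sets[n] for n in sorted(alive)}, descriptions=sets.descriptions)
    return out, removed_log


def build_term_network(
    sets: GeneSetCollection,
    annotations: Mapping[str, float] | None = None,
) -> nx.Graph:
    """Graph of terms with shared-gene counts as edge weights.

    Every term is a node (annotated with its set size and, when given, a
    score such as the sign-imbalance z); an edge joins two terms iff they
    share at least one gene, weighted by the shared-gene count.
    """
    graph = nx.Graph()
    annotations = annotations or {}
    for name in sorted(sets):
        graph.add_node(name, size=len(sets[name]), score=annotations.get(name))
    for a, b in itertools.combinations(sorted(sets), 2):
        shared = len(sets[a] & sets[b])
        if shared >= 1:
            graph.add_edge(a, b, weight=shared)
    return graph


def cluster_terms(graph: nx.Graph, patience: int = 10) -> dict[str, int]:
    """Edge-betweenness (Girvan-Newman) communities, cut at maximal modularity.

    Candidate partitions are the connected components plus successive
    Girvan-Newman splits; the partition with the highest weighted modularity
    wins.  The dendrogram walk stops once modularity has failed to improve
    for ``patience`` consecutive splits (modularity along the Girvan-Newman
    sequence is unimodal in practice, and the full walk is quadratic in the
    edge count).  Isolated nodes end up as singleton clusters; an edgeless
    graph is all singletons.
    """
    if graph.number_of_nodes() == 0:
        return {}
    if graph.number_of_edges() == 0:
        return {node: i for i, node in enumerate(sorted(graph.nodes))}
    best = [frozenset(c) for c in nx.connected_components(graph)]
    best_q = nx.community.modularity(graph, best, weight="weight")
    stale = 0
    for partition in nx.community.girvan_newman(graph):
        part = [frozenset(c) for c in partition]
        q = nx.community.modularity(graph, part, weight="weight")
        if q > best_q:
            best, best_q, stale = part, q, 0
        else:
            stale += 1
            if stale >= patience:
                break
    labels: dict[str, int] = {}
    for i, community in enumerate(sorted(best, key=lambda c: sorted(c)[0])):
        for node in community:
            labels[node] = i
    return labels


def clusters_to_frame(labels: Mapping[str, int]) -> pd.DataFrame:
    return pd.DataFrame(
        sorted(labels.items()), columns=["term_id", "cluster"]
    )


def edges_to_frame(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        {"term_a": a, "term_b": b, "weight": d["weight"]}
        for a, b, d in sorted(graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["term_a", "term_b", "weight"])
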