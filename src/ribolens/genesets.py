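"""Gene-set shift statistics with permutation nulls.

Two families of statistics quantify whether a gene set sits unusually high
or low in a ranked gene list:

* the classic unweighted running-sum enrichment score (ES): walking down the
  ranked list, the running sum rises by sqrt((N-G)/G) at each set member
  ("hit") and falls by sqrt(G/(N-G)) at each non-member, where N is the list
  length and G the number of set members in the list; the ES is the signed
  deviation of maximal absolute value.  With these step sizes the sum
  returns to zero at the end of the list, so the ES of a random set is
  centred near zero.
* the mean-rank statistic: the mean rank of the set's members (midranks on
  ties), compared with random same-size draws from the list.

Significance for both comes from permutation: scrambled gene labels are
equivalent to drawing random same-size sets, and the two-sided p-value uses
the add-one (Phipson-Smyth) estimator (1 + #{|null| >= |obs|}) / (n_perm + 1)
so that p = 0 never occurs.  Mean-rank statistics are centred at the
exchangeable expectation (N + 1) / 2 before taking absolute values.

Per-gene shift tests (e.g. a ribosomal-protein set against everything
detected) use a plain two-sample z test; a size-matched random-set reference
is available for the variant where the null is built from random sets with
the same number of genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_NULL_CHUNK = 256  # permutations per vectorized block; caps memory at ~N*chunk floats


class GeneSetCollection(dict):
    """Named gene sets (name -> frozenset of gene ids) with optional descriptions."""

    def __init__(self, sets: Mapping[str, Iterable[str]] | None = None, descriptions=None):
        super().__init__()
        self.descriptions: dict[str, str] = dict(descriptions or {})
        for name, members in (sets or {}).items():
            self[name] = frozenset(members)

    def filter_by_size(
        self,
        universe: Iterable[str] | None = None,
        min_size: int = 1,
        max_size: int | None = None,
    ) -> "GeneSetCollection":
        """Restrict sets to a universe, then keep those within [min_size, max_size]."""
        uni = None if universe is None else frozenset(universe)
        out = GeneSetCollection(descriptions=self.descriptions)
        for name, members in self.items():
            eff = members if uni is None else members & uni
            if len(eff) >= min_size and (max_size is None or len(eff) <= max_size):
                out[name] = eff
        return out


@dataclass
class RankedList:
    """A gene list ordered by a ranking metric, rank 1 at the head.

    ``orientation='descending'`` puts the largest metric first (the usual
    choice for log2 fold changes); ``'ascending'`` the smallest (e.g. CDS
    length with shortest genes on top).  Ordering ties break on gene_id so
    the list is deterministic; ``midranks`` carries midranks of the metric
    for mean-rank statistics.
    """

    genes: np.ndarray
    metric: np.ndarray
    midranks: np.ndarray

    @classmethod
    def from_metric(
        cls, values: pd.Series | Mapping[str, float], orientation: str = "descending"
    ) -> "RankedList":
        if orientation not in ("ascending", "descending"):
            raise ValueError(f"orientation must be ascending/descending: {orientation!r}")
        series = pd.Series(values).dropna()
        if series.index.duplicated().any():
            raise ValueError("duplicate gene ids in ranking metric")
        sign = 1.0 if orientation == "ascending" else -1.0
        order = sorted(series.index, key=lambda g: (sign * series[g], g))
        metric = series.reindex(order).to_numpy(float)
        midranks = stats.rankdata(sign * metric, method="average")
        return cls(genes=np.asarray(order, dtype=object), metric=metric, midranks=midranks)

    def __len__(self) -> int:
        return len(self.genes)

    def reversed(self) -> "RankedList":
        return RankedList(
            genes=self.genes[::-1].copy(),
            metric=self.metric[::-1].copy(),
            midranks=(len(self) + 1) - self.midranks[::-1],
        )

    def member_mask(self, gene_set: Iterable[str]) -> np.ndarray:
        members = frozenset(gene_set)
        return np.fromiter((g in members for g in self.genes), bool, len(self))


@dataclass
class SetStatResult:
    """One gene-set test outcome."""

    set_name: str
    set_size: int
    statistic_type: str  # ES | mean_rank | z
    observed: float
    null_mean: float
    null_sd: float
    p_nominal: float
    direction: str  # up | down (toward list head / away from it)
    p_adjusted: float | None = None
    metadata: dict = field(default_factory=dict)


def _es_steps(n: int, g: int) -> tuple[float, float]:
    if not 0 < g < n:
        raise ValueError(f"set must hit 1..N-1 genes of the list (G={g}, N={n})")
    return float(np.sqrt((n - g) / g)), float(np.sqrt(g / (n - g)))


def _es_from_mask(mask: np.ndarray) -> float:
    n = mask.size
    g = int(mask.sum())
    hit, miss = _es_steps(n, g)
    running = np.where(mask, hit, -miss).cumsum()
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    # signed deviation of maximal absolute value; exact ties go positive
    if abs(running[i_max]) >= abs(running[i_min]):
        return float(running[i_max])
    return float(running[i_min])


def gsea_es(ranked: RankedList, gene_set: Iterable[str]) -> float:
    """Unweighted running-sum enrichment score of a set in a ranked list."""
    mask = ranked.member_mask(gene_set)
    if not mask.any():
        raise ValueError("gene set disjoint from ranked list")
    return _es_from_mask(mask)


def _random_member_masks(n: int, g: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean (n_perm, n) matrix of random size-g sets (label scrambles)."""
    u = rng.random((n_perm, n))
    idx = np.argpartition(u, g - 1, axis=1)[:, :g]
    masks = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(masks, idx, True, axis=1)
    return masks


def _es_null(n: int, g: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    hit, miss = _es_steps(n, g)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(_NULL_CHUNK, n_perm - done)
        masks = _random_member_masks(n, g, k, rng)
        running = np.where(masks, hit, -miss).cumsum(axis=1)
        hi = running.max(axis=1)
        lo = running.min(axis=1)
        out[done : done + k] = np.where(np.abs(hi) >= np.abs(lo), hi, lo)
        done += k
    return out


def _mean_rank_null(
    midranks: np.ndarray, g: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    n = midranks.size
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(_NULL_CHUNK, n_perm - done)
        u = rng.random((k, n))
        idx = np.argpartition(u, g - 1, axis=1)[:, :g]
        out[done : done + k] = midranks[idx].mean(axis=1)
        done += k
    return out


def _addone_p(null_dev: np.ndarray, obs_dev: float) -> float:
    n_perm = null_dev.size
    return float((1 + int((null_dev >= obs_dev - 1e-12).sum())) / (n_perm + 1))


def permutation_null(
    ranked: RankedList,
    set_size: int,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    statistic: str = "es",
    observed: float | None = None,
) -> tuple[np.ndarray, float | None]:
    """Null sample of a set statistic from scrambled gene labels.

    Returns (null vector, two-sided add-one p for ``observed`` or None).
    ``statistic`` is 'es' or 'mean_rank'; mean-rank deviations are measured
    from the exchangeable expectation (N + 1) / 2.
    """
    n = len(ranked)
    if not 0 < set_size < n:
        raise ValueError(f"set_size must be in (0, N): got {set_size}, N={n}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if statistic == "es":
        null = _es_null(n, set_size, n_perm, rng)
        center = 0.0
    elif statistic == "mean_rank":
        null = _mean_rank_null(ranked.midranks, set_size, n_perm, rng)
        center = (n + 1) / 2
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    p = None
    if observed is not None:
        p = _addone_p(np.abs(null - center), abs(observed - center))
    return null, p


def gsa_mean_rank(
    ranked: RankedList,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    set_name: str = "",
) -> SetStatResult:
    """Mean-rank gene-set analysis with a random same-size-draw null.

    The observed statistic is the mean midrank of the set's members in the
    list; the null is the mean rank of random same-size draws without
    replacement.  Two-sided p by the add-one permutation estimator,
    deviations centred at (N + 1) / 2.  ``direction='up'`` means the set
    sits toward the head of the list (mean rank below expectation).
    """
    mask = ranked.member_mask(gene_set)
    g = int(mask.sum())
    if g == 0:
        raise ValueError("gene set disjoint from ranked list")
    n = len(ranked)
    if g >= n:
        raise ValueError("gene set covers the whole list")
    observed = float(ranked.midranks[mask].mean())
    null, p = permutation_null(
        ranked, g, n_perm=n_perm, seed=seed, statistic="mean_rank", observed=observed
    )
    expected = (n + 1) / 2
    return SetStatResult(
        set_name=set_name,
        set_size=g,
        statistic_type="mean_rank",
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        p_nominal=p,
        direction="up" if observed < expected else "down",
        metadata={"n_list": n, "n_perm": n_perm, "expected_rank": expected},
    )


def two_sample_z(
    values_in_set: Sequence[float], values_reference: Sequence[float]
) -> tuple[float, float]:
    """Two-sample z test for a difference in means (sample variances).

    z = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2); two-sided normal p.  Two
    zero-variance groups with equal means give z = 0, p = 1.
    """
    x = np.asarray(values_in_set, float)
    y = np.asarray(values_reference, float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    se2 = x.var(ddof=1) / x.size + y.var(ddof=1) / y.size
    diff = x.mean() - y.mean()
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    z = diff / np.sqrt(se2)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def size_matched_reference(
    values: pd.Series | Mapping[str, float],
    gene_set: Iterable[str],
    n_draws: int = 1000,
    seed: int | np.random.Generator | None = None,
    candidates: Iterable[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Random same-size gene sets as a reference distribution.

    Draws ``n_draws`` subsets, each the size of ``gene_set``, from all
    detected genes (or from ``candidates`` — e.g. a length stratum for a
    length-matched comparison).  Returns (pooled values across draws,
    per-draw means); the pool feeds :func:`two_sample_z` as its reference
    group, the per-draw means give an empirical p for the set mean.
    """
    series = pd.Series(values).dropna()
    members = frozenset(gene_set)
    g = len(members & set(series.index))
    if g == 0:
        raise ValueError("gene set disjoint from the value table")
    pool_index = (
        series.index.to_numpy()
        if candidates is None
        else np.asarray(sorted(set(candidates) & set(series.index)), dtype=object)
    )
    if g >= pool_index.size:
        raise ValueError("set size must be below the candidate pool size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = series.reindex(pool_index).to_numpy(float)
    n = vals.size
    pooled = np.empty(n_draws * g)
    draw_means = np.empty(n_draws)
    done = 0
    while done < n_draws:
        k = min(_NULL_CHUNK, n_draws - done)
        u = rng.random((k, n))
        idx = np.argpartition(u, g - 1, axis=1)[:, :g]
        block = vals[idx]
        pooled[done * g : (done + k) * g] = block.ravel()
        draw_means[done : done + k] = block.mean(axis=1)
        done += k
    return pooled, draw_means


def adjust_fdr(p_nominal: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_nominal, float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1] with no missing values")
    return multipletests(p, method="fdr_bh")[1]


def attach_fdr(results: Sequence[SetStatResult]) -> list[SetStatResult]:
    """Fill ``p_adjusted`` across one family of set results (BH)."""
    adj = adjust_fdr([r.p_nominal for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return list(results)


def results_to_frame(results: Sequence[SetStatResult]) -> pd.DataFrame:
    rows = [
        {
            "set_name": r.set_name,
            "set_size": r.set_size,
            "statistic_type": r.statistic_type,
            "observed": r.observed,
            "null_mean": r.null_mean,
            "null_sd": r.null_sd,
            "p_nominal": r.p_nominal,
            "p_adjusted": r.p_adjusted,
            "direction": r.direction,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
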