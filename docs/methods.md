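# Methods

This note documents the statistical procedures ribolens implements, the
parameters that matter, the synthetic study conditions used to validate
them, and the numerical choices made where the design was genuinely open.

## Gene-set shift statistics

**Ranked lists.** A contrast's genes are ordered by a metric (log2 fold
change by default; CDS length for the length-ranked analyses) with rank 1
at the head. Ordering ties break on gene id so lists are deterministic;
mean-rank statistics use midranks of the metric, so tied genes share a
rank in the standard nonparametric way.

**Running-sum enrichment score.** For a set with G of N list genes, the
running sum rises by √((N−G)/G) at each member and falls by √(G/(N−G)) at
each non-member; with these steps the walk ends at zero, so a random set's
score is centred near zero. The ES is the signed deviation of maximal
absolute value. This is the classic unweighted (Kolmogorov–Smirnov-style)
form; no fold-change weighting is applied, though the module is structured
so a weighted mode could be added. When the walk's maximum and minimum
have *exactly* equal magnitude the sign of the ES is genuinely ambiguous:
list reversal negates and reverses the walk, which can map such a path to
itself, so no deterministic sign rule can be exactly antisymmetric there.
ribolens resolves exact ties toward the positive extreme; the magnitude is
always reversal-invariant and the sign flips on every non-tied input.

**Mean-rank statistic and permutation null.** The observed statistic is
the mean midrank of the set's members. Scrambling gene labels is
equivalent to drawing random same-size sets without replacement, which is
how the null is sampled (vectorised in blocks of 256 permutations).
Deviations are measured from the exchangeable expectation (N+1)/2 — exact
for midranks — and the two-sided p-value uses the add-one estimator
p = (1 + #{|null − μ| ≥ |obs − μ|})/(B + 1), which cannot return zero and
is exactly uniform on its grid under the null. `direction = "up"` means
the set sits toward the head of the list. Default B = 1000 permutations;
B = 199 is used in high-replicate validation loops where the estimator's
0.005 grid resolution is sufficient.

**Two-sample z tests.** z = (m₁ − m₂)/√(s₁²/n₁ + s₂²/n₂) with sample
variances and a two-sided normal p. Two reference modes are provided,
because both appear in practice: the set against *all* detected genes
(default), and the set against values pooled from size-matched random
sets (`size_matched_reference`, which also returns per-draw means for an
empirical p). With the set a small fraction of the universe the overlap
between "set" and "all" is negligible; the size-matched mode exists for
exact like-for-like comparisons and accepts a candidate stratum (e.g. a
CDS-length band) for length-matched controls. Degenerate inputs: two
zero-variance groups with equal means give z = 0, p = 1.

**FDR.** Benjamini–Hochberg step-up within one result family, via
statsmodels. Ingested adjusted-p columns are used as-is; missing adjusted
p-values count as non-significant (upstream independent filtering).

## Sign-imbalance term scores and networks

For one functional term, z = (n_up − n_down)/√n_total over the term's
detected genes, bounded by ±√n_total; an all-up term of size n scores
exactly √n. Which genes count as up/down is configurable because the
upstream convention is ambiguous: the default counts every detected gene
by fold-change sign (exact zeros in neither group); a significance-gated
mode counts only genes with adjusted p below a threshold. A family of
terms of interest is compared against the scores of all detected terms
with the two-sample z test.

For network views, terms sharing ≥90% of their genes (fraction measured
against the smaller set, the natural reading of "shares 90% of its
genes") are pruned: violating pairs are scanned by descending overlap
fraction then term id, and the smaller term (tie: lexicographically
later) is removed — deterministic, idempotent, and leaving no surviving
pair above threshold. Edges carry shared-gene counts as weights;
communities come from Girvan–Newman edge betweenness, cutting the
dendrogram at maximal weighted modularity. The walk stops early once
modularity has not improved for 10 consecutive splits, since the sequence
is unimodal in practice and the full walk is quadratic in edges.

## CDS-length bias

Bins default to {0, 1000, 2000, 4000, ∞} nt of CDS and are half-open
[lo, hi), so a 1000-nt CDS falls in the 1–2 kb bin (the boundary is not
fixed by the usual "<1 kb / 1–2 kb" phrasing; this convention is
documented and configurable). Pairwise bin comparisons use the two-sample
KS statistic d = sup|ECDF₁ − ECDF₂| with the asymptotic two-sided p.

The top-N comparison (N = 500 by default) selects the most up- and
downregulated genes either by log2 fold change or by nominal p within
each fold-change sign ("pvalue_signed"), then z-tests log2 CDS length for
up-vs-all, down-vs-all and up-vs-down. The "all" reference is the whole
detected universe *including* the selected genes (recorded in the output
metadata); lengths are log2-transformed by default, with a raw-scale
option.

The length-ranked GSA builds two lists — shortest gene first and longest
gene first — filters terms to 20–50 detected members, runs the mean-rank
statistic per term in both orientations, and reports the top 7 terms per
orientation ordered by p then enrichment magnitude (relative deviation of
the observed mean rank from (N+1)/2).

The 2×2 length-group table splits a gene set at CDS length ≥ 2¹¹ nt and
gene span ≥ 2¹⁶ nt, with ≥ on the high side at the exact threshold
(documented, arbitrary) — used to ask whether coding or genomic length
drives an expression change.

## Annotation and expression filtering

One transcript represents each gene: the one with maximal TPM in the
reference tissue, ties broken to the lexicographically smallest
transcript id so the choice is reproducible; all-zero genes keep a
transcript under the same rule but are flagged. GC content of the CDS
excludes N bases from numerator and denominator, and an all-N sequence is
missing, not zero. The expressed-gene filter is strictly greater than the
threshold (default 2 FPKM). Both TPM and FPKM are carried, since
transcript choice and expression filtering conventionally use different
units. When no CAGE data are available, 5'UTR length can fall back to the
annotated transcript-start→coding-start distance so length analyses stay
runnable. Coordinates are 0-based half-open internally; GTF is converted
at the reader boundary.

## CAGE TSS calling

Counts are single-base 5'-end anchors; no smoothing is applied (none is
defensible without a calibration dataset, and the synthetic signal is
single-base). The scan window runs, in transcription order, from 1000 nt
upstream of the earliest annotated transcript start to the **latest**
coding start. Ending at the earliest coding start would be the minimal
window containing all *callable* outcomes, but it would make the
downstream-TSS exclusion rule unreachable: a maximum found there is
automatically upstream of every coding start. Extending to the latest
coding start lets the caller observe a pileup that lies between two
transcripts' coding starts — exactly the situation the exclusion rule
exists to catch. Pileup ties resolve to the position closest to the
coding start (most downstream on the gene strand): deterministic, and
conservative in producing the shortest 5'UTR.

Assignment then picks, among transcripts whose coding start is strictly
downstream of the TSS, the one at minimal distance; that distance is the
5'UTR length. A TSS at or downstream of *any* coding start excludes the
gene (`excluded_downstream`; a 0-nt 5'UTR is treated as degenerate and
excluded), and a 5'UTR over 500 nt excludes it as `excluded_long_utr`.
Genes with no reads in the window are `no_signal`.

## Synthetic study conditions

The generator's defaults describe a hippocampal-scale screen and are the
conditions under which the package's statistical claims are validated:

| parameter | default | meaning |
|---|---|---|
| n_genes | 12000 | detected protein-coding genes |
| cds_meanlog, cds_sdlog | 7.2, 0.6 | lognormal CDS length (median ≈ 1.3 kb, right-skewed) |
| utr5 / utr3 lognormal | (4.8, 0.7) / (6.2, 0.8) | median ≈ 120 nt and 490 nt |
| rp_set_size | 80 | RP-like set, drawn from the shortest CDS tercile |
| beta_len | −0.05 | slope of true log2fc on centred log2 CDS length |
| gamma_rp | +0.3 | additive log2fc shift of the RP-like set |
| sigma_noise | 0.15 | per-gene biological spread of the true log2fc |
| se_scale, n_replicates | 0.08, 4 | per-gene SE scale; inverse-chi degrees of freedom |
| nb_dispersion, library_size | 0.05, 3×10⁶ | negative-binomial counts for paired TRAP/total |
| cage_signal_mean, cage_background | 50, 0.05 | Poisson spike at the true TSS; per-base background |
| decoy_fraction, long_utr_fraction | 0.10, 0.05 | planted exclusion-rule cases |

`sigma_noise` lives in the *true* fold changes (biological spread);
measurement noise enters separately as se·ε with per-gene standard errors
from a scaled inverse-chi law, so that `SimulationConfig.null()` (all
three effect parameters zero) yields exactly uniform p-values, and the
noiseless limit (sigma_noise = 0, se_scale = 0) reproduces the
deterministic effect structure exactly.

What the generator emulates: skewed length distributions, a short-biased
upregulated set, a length-dependent trend, paired overdispersed counts,
and pileups with known TSS including both exclusion cases. What it does
not: multi-exon gene structure in the CAGE fixtures (single-exon models),
correlated gene-gene expression, isoform switching, batch structure, or
read-level artefacts. Passing tests therefore demonstrate the statistics
are correct and calibrated under the assumed effect structure, not that
any particular biological dataset satisfies that structure.

CAGE fixtures cover the first 300 universe genes by default (the caller
is O(genes), so this bounds fixture size without affecting the per-gene
logic being tested); genes alternate strands along one synthetic
chromosome with ≥2-window spacing so scan windows never collide.

## Validation problem sizes

The automated checks use: null calibration with 2000–4000 replicate
random sets (G = 20 of N = 500 for the mean-rank statistic at B = 199;
G = 80 of N = 4000 for the z test), chosen so the binomial error on a 5%
rate is ≈0.3–0.5%; effect recovery across 50–100 independent seeds at the
full default universe; oracle equivalence on 100 random small instances
per statistic against independent brute-force implementations (exact for
discrete statistics, 1e-12 relative tolerance for continuous); and TSS
validation on 300-gene fixtures with and without background.

## Known limitations

- The Girvan–Newman early stop (patience 10) could in principle miss a
  later modularity maximum on pathological networks.
- The hypergeometric overlap test takes the universe as a size, not a
  membership list, so subset validation is limited to cardinality.
- The GTF writer supports the single-exon models the generator emits;
  multi-exon models are read but not written.
- Per-gene TRAP/total ratios are exposed descriptively; no second-stage
  model is fit on them.
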