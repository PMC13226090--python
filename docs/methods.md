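# Methods

`tmecrossmap` implements a cross-species comparison pipeline for tumor
microenvironments (TMEs): discovery of gene expression programs (GEPs) by
consensus nonnegative matrix factorization (cNMF), cross-species program
matching, compositional archetype mapping, cross-compartment ligand scaling,
and survival stratification by program scores. Every stage is exercisable on
synthetic cohorts with planted ground truth; this note records the models,
the defaults that matter, and the choices made where the design was open.

## Consensus NMF program discovery

**Model.** Expression `X` (genes × samples, nonnegative) is approximated as
`X ≈ W·H` with `W ≥ 0` (gene weights per program) and `H ≥ 0` (program usage
per sample). Input is log2(x+1)-transformed and restricted to the most
variable genes by median absolute deviation (default 5,000; MAD ties broken
by gene id so the selection is deterministic).

**Solver.** Frobenius-loss multiplicative updates with seeded uniform
nonnegative initialization (`nmf.nmf_run`). The objective is monotone
non-increasing and is monitored every 10 iterations; a run stops when the
decrease falls below `tol·‖X‖` (default 1e-6) or at `max_iter` (default
500). The solver sits behind the `nmf_run` boundary and is swappable.
Multiplicative updates converge slowly near a noiseless optimum; tests that
require near-exact reconstruction pass a deeper budget explicitly.

**Rank selection.** For each rank, `runs_per_rank` factorizations at
distinct derived seeds produce connectivity matrices (sample co-assignment
by argmax usage, ties to the lowest factor index); their mean is the
consensus matrix. Stability is the cophenetic correlation coefficient
(CCC): the Pearson correlation between the condensed distances
`D = 1 − consensus` and the cophenetic distances of average-linkage
hierarchical clustering of `D`. A perfectly reproducible partition yields a
0/1 block consensus, which is ultrametric, hence CCC = 1. The sweep repeats
this `repeats` times per rank and reports the median CCC; candidate ranks
are strict interior local maxima of the median-CCC curve (plateaus count
their leftmost rank, endpoints are excluded). Sweep-stage runs cap
multiplicative updates at 200 iterations: argmax factor assignments
stabilize long before the factors converge, and the sweep only consumes
assignments.

**Consensus factorization.** At a chosen rank k: 10 seeded runs; every
factor's gene-weight column is L2-normalized with the scale moved into its
usage row (NMF is scale-ambiguous per factor); the 10·k usage vectors are
clustered by k-means (k clusters, 10 seeded restarts); within each cluster a
local outlier factor (LOF) filter with `n_neighbors = min(5, size−1)` and
contamination 0.40 removes aberrant members (single-member clusters are not
pruned; contamination 0 disables pruning, which the robustness experiments
use as the control); element-wise medians of the retained members give one
consensus column of `W_Con` and row of `H_Con`, re-normalized to unit L2
gene weights. Clustering is on usage vectors by default; `cluster_on="W"`
clusters gene-weight vectors instead.

**Numerical notes.** Per-run seeds derive from
`SeedSequence([seed, rank, repeat, run])`, so sweeps are reproducible and
order-independent. A consensus matrix whose off-diagonal distances are all
equal has no clustering structure; its CCC is undefined and reported as
missing with a warning.

## Cross-species program matching

Program signatures are the top-n genes by consensus weight (ties by gene
id); n = 20 is the default for T-cell-sized panels, 50 suits broader myeloid
programs. For cross-species comparison the second species' signature is
translated through a one-to-one ortholog map (genes mapped ambiguously or
not at all drop out). Similarity is the Jaccard index of the translated
sets; significance is a two-sided Fisher exact test on the 2×2 overlap
table. The Fisher universe defaults to the number of one-to-one mapped
genes — only genes observable in both analyses can overlap; any other
universe can be passed explicitly. No multiple-testing correction is
applied to the match table by default (a BH option exists).

## Compositional archetype mapping

Compartment-frequency tables (fractions of 10 cellular compartments per
sample) are z-scored with pooled per-feature moments across all cohorts
jointly — never per cohort — so cohorts land on one scale; zero-variance
features map to zero. Group profiles are per-feature medians by default
(means available). Cosine similarity between group profiles normalizes each
row to unit length and takes the matrix product with the transpose; distance
is 1 − similarity. "Relative variance" is computed as population variance
divided by the squared mean (CV²) on raw frequencies: scale-free, so
features of different magnitudes are comparable; a zero group mean leaves it
undefined (reported missing). Cell-density relationships use Pearson
correlation with two-sided p from the t-transform of r,
pairwise-complete observations, and Benjamini–Hochberg adjustment over all
tested off-diagonal pairs jointly; constant features are excluded from the
BH family rather than given placeholder p-values.

## Cross-compartment expression scaling

Bulk count libraries are normalized by trimmed mean of M-values (TMM):
reference = sample whose upper quartile of nonzero counts is closest to the
mean upper quartile; 30% M-trim and 5% A-trim; inverse-asymptotic-variance
weights; factors rescaled to geometric mean 1; counts-per-million on
factor-adjusted library sizes. The implementation agrees with
edgeR's `calcNormFactors(method="TMM")` to ~1e-11 on a frozen fixture.
Upper-quartile normalization divides each sample by its 75th-percentile gene
count and applies log2(x+1). Single-cell data are pseudobulked by arithmetic
means per (compartment, sample) group. Each species is then z-scored per
gene across its own compartments (population SD; zero-variance genes → 0);
cross-species comparison happens only after this within-species scaling, via
one-to-one ortholog harmonization that reports retained/unmapped/ambiguous
gene counts. Log transforms use log2(x+1) throughout.

## Movements and survival

Program "gene scores" replace each signature gene's expression by its
fractional rank across samples (rank/n, ties averaged) and average over the
signature — invariant to any monotone per-gene transformation. Scores can
equally come from `H_Con` rows; both feed the same downstream operations.
T-versus-myeloid "movements" are Pearson correlations between the two score
matrices over shared samples, BH-adjusted over all pairs. Subjects are
binned per program by score quantiles (median split by default; 0.3/0.7 for
gene-score cohorts), ties falling to the lower bin; joint labels cross the
per-program bins. Survival uses the product-limit (Kaplan–Meier) estimator
with right censoring and the unweighted log-rank test.

**Small-sample log-rank calibration.** The chi-square asymptotic for the
log-rank p is visibly miscalibrated in tiny cohorts: across random n = 12
two-group fixtures its p deviates from the exact permutation p by ~0.02–0.03
(median) and up to ~0.05. `logrank_test` therefore computes an exact p by
enumerating all group assignments whenever there are two groups and at most
10,000 assignments (n = 12 balanced → 924), and falls back to the asymptotic
otherwise. The permutation oracle used in tests is an independently written
Monte-Carlo engine, not the production path.

## Synthetic cohorts and what they do (not) show

The generators define the study conditions for all tests:

* **Planted GEP datasets** (default 1,000 genes × 200 samples per species,
  k_true = 6 programs of which 3 shared, 30 exclusive marker genes per
  program with weights in U(2,6) over U(0,0.05) background). Shared programs
  place identical marker weights on ortholog-paired genes, so their mapped
  top-20 sets have ground-truth Jaccard 1; species-specific programs use
  disjoint marker blocks. Usages are gamma draws with one dominant program
  per sample (cycled so all programs are populated) plus up to two weaker
  secondary programs — the program-dominance structure consensus clustering
  assumes. Noise is Gaussian with SD = `noise_scale` × mean signal, clipped
  at zero (moderate = 0.5), or rescaled Poisson. The ortholog map drops 5%
  of non-marker genes and makes 2% many-to-many to exercise the filtering
  policy.
* **Frequency cohorts** are Dirichlet draws with parameter
  `concentration × centroid` (default concentration 80–200 depending on the
  analysis; higher = tighter groups). Shipped centroids encode immune-rich
  (CD8- or CD4-dominated), stromal, and macrophage-rich / low-infiltration
  immune-desert classes, plus mouse-model centroids that are mostly
  macrophage-biased deserts with one highly infiltrated outlier.
* **Survival cohorts** draw exponential event times with rate
  `baseline_hazard · exp(Σ coef·score)` and per-subject exponential
  censoring calibrated so each subject is censored with probability
  `censor_rate`.

These cohorts are clean by construction: no batch effects, no
compositional coupling between expression and frequencies, no
library-size confounding, exclusive marker genes, and exponential (i.e.
proportional-hazards-faithful) survival. Passing tests therefore demonstrate
that the machinery recovers structure it is designed for; they do not
establish robustness to the messier failure modes of real cohorts
(overlapping programs, batch structure, informative censoring).

## Problem sizes

Recovery experiments run at 1,000 genes × 200 samples with ranks 3–12, 10
runs per rank and 3 repeats, 10 replicate datasets for rank recovery and 10
for the LOF-corruption comparison; archetype mapping uses 100 cohort
replicates; the movement/survival experiments use n = 100–150 subjects.
These desk-scale sizes keep a full verification run in minutes while leaving
every recovery margin comfortably wide of its threshold.

## Known limitations

* The NMF solver is plain multiplicative updates; it is deliberately simple
  and deterministic, not fast or state-of-the-art (no HALS/anls, no
  sparsity penalties).
* CCC follows the canonical consensus-clustering definition
  (average-linkage cophenetic correlation on 1 − consensus); other
  stability scores (dispersion, silhouette) are not implemented.
* The match table's Fisher test treats signatures as fixed gene sets;
  weight magnitudes beyond the top-n cut do not contribute.
* UMAP embedding of z-scored compositions is display plumbing only and is
  excluded from numeric guarantees.
* Survival tooling covers KM and log-rank only; no Cox modeling or
  covariate adjustment.
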