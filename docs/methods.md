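# Methods

`nhoodde` tests for condition-associated differential expression (DE) without
clustering cells into discrete types.  Cells are grouped into overlapping
neighborhoods on a kNN graph of a pre-computed latent embedding, each
neighborhood is tested with a pseudo-bulk negative-binomial (NB)
quasi-likelihood (QL) model, and p-values are corrected in two directions.
This note records the model, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Graph and neighborhoods

**Distance and graph.** Distances are Euclidean in the supplied latent space
(the package never builds embeddings; any batch-corrected PCA/MNN/scVI-style
space works).  The 1st-order graph links each cell to its `k` nearest
neighbors (self excluded) and is then symmetrized (an edge exists if either
direction was selected).  The 2nd-order graph adds an edge between any two
cells sharing at least one common neighbor in the symmetrized 1st-order
graph.  Second-order edges are a strict superset of first-order edges, so
neighborhood sizes grow much faster with `k`; `order=2` with `k` around 20–25
typically yields average neighborhoods above the ~350-cell size at which the
pseudo-bulk test becomes sensitive, while keeping rare, tightly clustered
populations in their own (smaller, purer) neighborhoods.

**Index cells.** Neighborhood centers are chosen by waypoint sampling:
`floor(prop * n)` cells are sampled uniformly without replacement
(default `prop = 0.2`); for each sampled cell the induced subgraph on the
cell and its neighbors is extracted (always on a shallow 1st-order graph with
`k' = min(50, k)`, reused as the assignment backbone when `k <= 50`), each
vertex's 3-cycle (triangle) count is computed, and the vertex with the most
triangles becomes the index cell.  Duplicates collapse.  Each neighborhood is
the index cell plus all its graph neighbors, so neighborhoods overlap and are
in bijection with their index cells.

**Tie-breaks (all deterministic given the seed).** Equal kNN distances break
by ascending cell index; equal triangle counts prefer the originally sampled
cell, then the lowest index; equal sizes during refinement break by ascending
neighborhood index.  The kNN tie rule matters only for duplicated or
symmetric coordinates; we do not perturb ties.  Waypoint candidates are
sampled once, jointly — a cell already chosen as an index cell by an earlier
candidate can be chosen again (and collapses).

**Refinement.** Choosing the smallest `prop` that still covers every cell is
not knowable in advance, so an excess of neighborhoods is assigned and then
reduced by a greedy set cover: neighborhoods sorted by decreasing size, kept
only if they contain a not-yet-covered cell.  The kept set covers exactly the
cells the input covered; greedy covering is within the standard `ln n` factor
of the (NP-hard) optimum.

## Per-neighborhood testing

For each neighborhood, counts of its cells are summed per biological sample.
Samples contributing fewer than `min_n_cells_per_sample` (default 3) cells
are dropped; a neighborhood with fewer than two remaining samples, a missing
condition level, or a rank-deficient design after dropping is *untested*
(NaN in all output matrices), never an error.

**Gene filtering.** A gene is tested if its CPM exceeds the CPM equivalent of
`min_count` (default 3) at the median library size in at least `n_min`
samples, where `n_min` is the size of the smaller condition group, and its
total count is at least 15 (the cited sufficient-counts rule's default
`min.total.count`, which the interface deliberately does not expose).
`min_count = 0` disables filtering.  Library sizes are totals over the
*selected* genes of the *neighborhood*, so they are neighborhood-specific.

**Normalization.** Trimmed-mean-of-M-values (TMM) factors correct
compositional bias: the reference sample has the upper-quartile count
fraction closest to the mean; M-values are trimmed 30 % and A-values 5 %,
combined by precision (delta-method) weights, and factors are rescaled to
geometric mean 1.  Offsets are `log(lib_size * factor)`.

**Dispersion.** NB dispersions are estimated per gene by maximizing the
Cox–Reid adjusted profile likelihood on a 13-point log-spaced grid
(1e-4 … 10) with quadratic interpolation of the maximum; a lowess trend
(span 0.4) on average log-CPM captures the mean–dispersion relationship, and
tagwise values shrink the gene-wise estimates toward the trend on the log
scale with precision weights `res_df/(res_df + prior_df)`.  The prior df is
moment-matched — the sampling variance of a log-dispersion estimate is taken
as `2/res_df` and the excess spread of residuals around the trend defines the
prior variance — and floored at 3 for stability on tiny neighborhoods.

**QL F-test.** A log-link NB GLM (IRLS, vectorized across genes) with the
tagwise dispersion and the design `intercept + covariates + condition` is
fitted, plus the reduced model without the condition column.  The per-gene
quasi-dispersion is the mean residual deviance (floored at 1e-8), squeezed by
empirical Bayes: `s2 ~ s2_0 * F(res_df, d0)` with `(d0, s2_0)` estimated by
moment matching of `log s2` (trigamma inversion).  The test statistic is
`F = (deviance_reduced - deviance_full) / s2_post` on `(1, d0 + res_df)`
degrees of freedom.  `logFC` is the unshrunken condition coefficient in log2
units, positive meaning higher in the case level; no prior count is added.
Under a simulated global null the raw p-values are uniform to within
KS distance 0.05 and the type-I error at nominal 0.05 stays below 0.07
(verified in the test suite).

**Classifier pre-filter (optional, off by default).** Per neighborhood, a
random-forest classifier predicts the condition from log1p counts scaled to
the median library size, on balanced subsamples of up to 50 cells per
condition with 3-fold stratified cross-validation repeated 3 times; the mean
AUC is reported.  The subsample size, fold count and repeat count are our
choices — the adapted classifier approach does not pin them down.
Neighborhoods under the AUC threshold (recommended 0.5) are skipped;
neighborhoods too small to cross-validate (under 3 cells in either
condition) keep AUC = NaN and are retained.  The filter is a compute saver
and should be avoided when batch effects are unbalanced.

## Dual multiple-testing correction

Within each neighborhood, BH across its tested genes.  Within each gene, a
*weighted* BH across its tested neighborhoods: sorted ascending, the adjusted
value at rank i is `min over j >= i of p_(j) * W / C_(j)` with `W` the total
weight and `C_(j)` the cumulative weight, clipped at 1.  The suffix-min
formulation makes the result independent of tie order.  Weights are the
reciprocal of the neighborhood's graph density — the sum over member cells of
the number of neighborhoods each cell belongs to — computed on the *refined*
assignment actually tested (cell multiplicities before refinement would count
discarded neighborhoods that produce no tests).  Untested entries contribute
neither to `W` nor to `C` and pass through as NaN.  Equal weights reduce the
procedure exactly to textbook BH.

## Synthetic data generator

The generator follows the standard hierarchical NB model for scRNA-seq
counts: library sizes `L_c ~ LogNormal(9.3, 0.25)` (≈ 11 000 counts/cell),
gene base means `λ_g ~ Gamma(shape 0.6, rate 0.3)`, lognormal DE factors
(`de_facLoc`, `de_facScale = 0.4`) applied with probability `de_prob` and
random direction (factor or its reciprocal) to non-reference cell groups,
optional lognormal batch factors, per-cell expected proportions rescaled to
`L_c`, and a BCV dispersion `φ_g = (0.4 + 1/√mean_g)^2 * bcv_df / χ²(22)`.
Defaults (4 000 genes, 10 replicates per condition, 200 cells per replicate)
aim at mouse-embryo-like marginals and are the conditions under which the
acceptance benchmarks run.  The embedding is the top 10 PCs of log1p-CPM,
making benchmarks self-contained.

Two group semantics cover the benchmark designs: `by_condition` ties two
groups to the case/control conditions (condition-associated DE in `de_prob`
of genes, effect recorded as the true log2 factor); `random` draws sub-cell
types per cell from `group_fractions` with no intrinsic condition effect.

**What the generator does not emulate:** dropout beyond NB sampling,
zero-inflation, doublets, ambient RNA, cell-cycle structure, or continuous
trajectories.  Passing benchmarks therefore demonstrate the statistical
machinery under a realistic NB regime, not robustness to every artifact of
real data.

## Benchmarks

**Power vs number of cells.** One two-condition dataset (25 % DE genes,
lognormal effects), 200 random cell subsets of sizes uniform in [50, 3000];
per draw the pseudo-bulk QL test at raw p < 0.05; running median (clipped at
the edges) over draws sorted by size.  The default smoothing window covers
5 % of the draws — 101 draws at the reference budget of 2000 — so that it
spans a comparable band of subsample sizes at any draw budget; a window
fixed in draws would stop being local in cells when fewer draws cover the
same size range (at 200 draws a 101-draw window spans ~±750 cells and the
"median at 350" would actually report power near 600 cells).  Sensitivity is
reported *conditional on effect size*: the power "to detect logFC = 1" is
measured on true-DE genes whose realized |log2FC| falls in 1 ± 0.25 (and
2 ± 0.25 for logFC = 2) — pooling over the whole lognormal effect
distribution would mix effect sizes and mostly reflect its upper tail.  The
bin half-width 0.25 is our choice.  At ~350 cells this yields roughly
65–80 % (logFC 1) and ~80 % (logFC 2) with 10 replicates per condition; the
estimate carries noticeable dataset-level variance (±5 points across
simulation seeds) because the expression levels of the few hundred genes in
an effect bin are frozen per dataset.

**Injection benchmark.** For perturbed-group fractions {0.01, 0.05, 0.25,
0.5} (5 replicates per condition simulated), uniform integer counts 0–3 are
added to the perturbed group's case cells for 9 candidate genes chosen so
the predicted pseudo-bulk contrast spans 1–5; the full pipeline runs
(order 2, k = 25, two independent assignments, `min_count = 0` since the
simulated panel is small); per gene the ROC AUC of `1 - p_adj_nhoods`
(untested = 1) against neighborhoods with perturbed-group purity above
0.1 / 0.25 is averaged, as is the single-cell AUC of decomposed z-scores
(`z = Φ⁻¹(1 - p_adj_nhoods)`, averaged over each cell's tested
neighborhoods) against the injected cells.  Each dataset is evaluated under
two replicate arms — all 5+5 samples, and a random 2+2 subset — because
detection with few biological replicates is the regime where neighborhood
testing is stressed; the intermediate 2+5/5+2 arms are omitted to keep the
benchmark within a desk-scale runtime.  Arms in which no neighborhood
reaches the purity threshold yield no AUC and are skipped by the average.
Two scale rules keep the benchmark honest at small fractions: the perturbed group gets a stronger
separation (de_prob 0.3, de_facLoc 2 below fraction 2.5 %, mirroring the
per-fraction calibration of the original experiment), and the dataset grows
so the expected group size stays at or above ~2.4·k — a group smaller than
`k + 1` cells *cannot* dominate any neighborhood, because every member is
forced to link outside the group and 2nd-order edges dilute it.

**Candidate genes.** Without ground truth, injection candidates are genes
showing no condition DE in any abundant cell type (per-type pseudo-bulk QL
test: BH FDR ≥ 0.5 and |logFC| < 0.25 everywhere, nonzero expression); the
FDR/logFC thresholds operationalize "not DE" and genes untested in a type
(too few counts there) are treated as unobjectionable.

## Downstream pattern analysis

"Corrected logFC" zeroes the logFC wherever the across-neighborhood corrected
p exceeds 0.1 or the combination was untested.  Neighborhood perturbation
ranking counts genes with `p_adj_genes < 0.1` and "specifically DE" genes
whose across-neighborhood p vector (untested = 1), standardized to mean 0 and
sample (n−1) sd 1, drops below z = −3 in the neighborhood.  Gene-set
discovery: genes significant in ≥ 25 % of neighborhoods, |mean significant
logFC| > 1, consistent direction in ≥ 75 % of neighborhoods; clustering by
PCA (5 PCs) of corrected-logFC vectors, an SNN graph with Jaccard weights
over 10 nearest neighbors (k and weighting are our choices; neighbor sets
include the point itself) and seeded Louvain at resolution 1.  Binning along
a per-neighborhood covariate (e.g. a differential-abundance logFC supplied
externally) uses equal-frequency bins (sizes differ by ≤ 1; an equal-width
mode is available by flag).  The Fisher classification builds, per gene, a
2×2 (DE / not-DE) × (group A / group B) table over two user-supplied
neighborhood groups, BH-corrects two-sided exact p-values across genes and
labels genes by direction at corrected p < 0.1; whether positive-DA
neighborhoods are excluded before grouping is left to the caller, which
passes the group flags explicitly.

## Degenerate inputs and numerical floors

NB deviance and likelihood use `log1p` forms stable down to dispersion
1e-10; fitted means are floored at 1e-8 and linear predictors clipped at
±50.  All-zero genes yield logFC 0 and p ≈ 1.  A sample with zero library on
the selected genes is dropped (with a re-check of testability).  Quasi-
dispersions are floored at 1e-8; the dispersion-shrinkage prior df at 3.
Lowess NaNs (duplicated extremes) fall back to the mean; fewer than 20 genes
use a constant trend.  `weighted_bh` requires positive finite weights and
passes NaN p through untouched.

## Known limitations

* Numerical agreement with the reference QL implementation is approximate by
  design (different grids, trend smoother and shrinkage estimator);
  correctness is asserted through calibration, symmetry and recovery
  properties instead of bit-equality.
* Overlapping neighborhoods propagate sporadic high counts from single cells
  into several tests; refinement and replicate numbers mitigate but do not
  remove this.
* The single-threaded per-neighborhood loop is adequate up to a few hundred
  neighborhoods × a few thousand genes; very large atlases would need
  batching.
* Differential-abundance testing is out of scope; DA logFC enters only as a
  per-neighborhood covariate supplied by the user.
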