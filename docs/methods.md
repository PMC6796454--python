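# Methods

This note documents the models, procedures and numerical choices behind
`gliosig`: what each stage computes, what the synthetic-data generator does
and does not emulate, and where a design was genuinely open.

## The analysis model

### Clustering diagnostics (HCPC + NMI)

Cells are embedded on the top principal components of the gene-centered
expression matrix (default 5 components, the conventional default of the
hierarchical-clustering-on-principal-components approach). Ward agglomeration
is computed on the component scores and cut at the number of clusters
`k ∈ [2, k_max=10]` that maximizes the relative loss of within-cluster
inertia between successive cuts, `Q(k) = (W(k−1) − W(k)) / (W(k) − W(k+1))`.
An optional k-means consolidation (initialized at the cluster centroids,
≤ 10 iterations) keeps the procedure deterministic. Component signs are fixed
so each component's largest-magnitude loading is positive; Ward ties are
resolved by scipy's deterministic nearest-neighbor-chain order, so identical
inputs always give identical partitions.

Agreement between a clustering and an external label is measured by
normalized mutual information computed from the contingency table with
natural logarithms and the square-root normalization
`NMI = I(A;B) / sqrt(H(A) H(B))`. NMI is 1 exactly when the partitions
coincide up to renaming and 0 when every cluster contains all labels in
identical proportions. If either partition has zero entropy (a single
cluster), NMI is defined as 0 and flagged degenerate rather than raising, so
degenerate clusterings cannot crash a treatment battery; the normalization
variant is recorded in the result so alternatives can be compared.

### The treatment battery

Each battery row reruns the identical clustering recipe on a transformed
matrix: raw log2(CPM+1); binarized (detected → 1); standardized per tumor
(gene-wise center/reduce within each tumor, sample SD, zero-SD genes → 0);
housekeeping-gene normalized (per-cell factor = geometric mean of value+1
over the housekeeping set, rescaled by the cohort median factor — a
robust-to-outliers form chosen because the published description leaves the
formula open); CNV-chromosome gene exclusion; exclusion of the top 100
inter-tumor DE genes (Kruskal-Wallis H ranking); top-500/1000 overdispersed
genes kept or excluded (bin-wise z-scored variance/mean in 20 equal-frequency
mean bins — a documented stand-in for the external method the field cites
without formulas); and a most-expressed filter (aggregate
`log2(mean linear CPM + 1) ≥ threshold`; the threshold is exposed because no
universal default exists). Metacell treatments are named hooks reported as
skipped: their construction is not described in the source methods.

### Gene down-sampling

For each gene-set size (default 2000, 1000, 500, 250, 100, 50) the clustering
is repeated on 10 random gene subsets; replicate NMIs are tested against a
reference NMI with a one-sample t-test (a zero-variance replicate set is
flagged and reported with p = 1). All sampling flows from one seed.

### Signature scoring and splits

The tumorigenic score of a cell is the geometric mean of the log2(CPM+1)
values of the signature genes, with *exact* zeros imputed to 1 before the
product (values in (0,1) are used as-is). Every signature gene must be
detected in ≥ 25% of cells (boundary inclusive). Cells are split at the
arithmetic mean of the score — the distribution's main inflection point in
the motivating data — with ties assigned to LOW (conservative, since HIGH is
the claim-bearing group). Smoother tissue-level distributions are split at
the extreme quartiles (type-7 linear interpolation; the middle half is
UNASSIGNED).

### Differential expression and metabolic selection

Per-gene two-sided Mann-Whitney tests compare HIGH vs LOW cells: exact
enumeration when both groups have ≤ 8 members, otherwise the tie-corrected
normal approximation. The continuity-corrected normal approximation agrees
with the exact test to < 0.01 in the decision-relevant range (p ≤ 0.2) at
8 vs 8; its absolute error peaks just above 0.01 at mid-range p, which is a
property of the approximation, not of the cutover. Benjamini-Hochberg
adjustment runs across all tested genes (the post-filter gene family);
direction (HIGH/LOW) is assigned only below the significance threshold, by
comparison of group means on the analyzed log2(CPM+1) scale. Metabolic
candidates are the significant HIGH-direction genes of an annotation set
whose expression is Pearson-correlated with the score at p < 0.01, ordered
by |r|.

### Network skeleton and hub

Pairwise mutual information (bits) between module genes uses plug-in entropy
after equal-frequency discretization (default 8 bins; equal-frequency rather
than equal-width for robustness to skewed expression). Genes with at most
8 distinct values keep one bin per value, and quantile edges tied at the
minimum are dropped, so heavily zero-inflated genes discretize sensibly.
Edges are retained when observed MI beats a per-pair permutation null
(default 200 permutations, add-one p-values) under BH control at q = 0.05;
each edge records its p and the null's 95th percentile. Note the permutation
count bounds the smallest achievable p at 1/(n_perm+1); with many tested
pairs and few true edges, too few permutations can push every BH-adjusted p
above q. The "densest node" is the top of the degree ranking (ties by summed
edge weight, then identifier). This skeleton deliberately replaces a full
multivariate-information causal reconstruction: no conditional-independence
pruning and no edge orientation, because the only claim consumed downstream
is the hub's identity.

### Principal curve

The curve follows the classic alternating scheme: initialize at the first
principal component, then repeat (project points onto the current polyline;
smooth each coordinate against arc-length with a lowess smoother of span
0.5, one robustness iteration) until the mean squared displacement of fitted
points falls below 1e-4 or 50 iterations. Consecutive duplicate vertices are
dropped so arc-length is strictly increasing. Projection is direct
nearest-point projection onto the polyline (no extra curve regularization).
Cell density along the curve is a Gaussian KDE (Silverman bandwidth by
default); overlays are sliding-window means over windows spanning 10% of the
arc-length. Curve orientation is intrinsically arbitrary; when an orientation
overlay is given, arc-length is flipped so the curve starts at the lower-mean
end of that overlay, making plots comparable across runs.

## The synthetic-data generator

The generator produces the statistical structure the analysis assumes, so
every stage is testable without downloads. Per cohort:

- **Gene abundance.** Base means are log-normal (`meanlog 1.0`, `sdlog 1.5`,
  natural-log units). Signature, module and housekeeping genes are drawn from
  a tight, boosted band (`meanlog + 4.3`, sd 0.4) so they are detected in
  nearly all cells, as the scoring contract requires. Lineage-marker genes
  get a `+1.0` boost.
- **Tumor identity, dispersed.** Every cancer cell of tumor *t* adds
  `δ(g,t) ~ Normal(0, 0.15)` log2 units to *every* gene — no tumor marker
  set exists by construction, mirroring the finding that tumor-driven
  grouping is irreducible to circumscribed gene groups.
- **Normal cells.** No expression-level tumor term; each of 3 lineages
  up-shifts its 40 marker genes by 1.0 log2 unit, so normal cells cluster by
  lineage.
- **Latent tumorigenic state.** `s ~ ½Beta(2,5) + ½Beta(5,2)` (bimodal on
  [0,1]; the fraction above 0.5 is ½ analytically). Signature genes shift by
  `1.0 × s` log2 units. A hub variable `h = s + Normal(0, 0.1)` drives the
  module: the hub gene shifts by `1.2 × s_effect × h` and each spoke by
  `β_j × h + Normal(0, 0.1)` with `β_j ~ Uniform(0.4, 0.9) × s_effect`,
  giving the hub the strongest coupling to every spoke and hence an
  unambiguous top weighted degree. The chain amplitudes are kept moderate so
  that 21 high-abundance state genes do not dominate the global PCA over the
  tumor axes.
- **Counts.** Expected counts are `library × softmax(log2 expression)` with
  log-normal library sizes (median 250,000 reads); observed counts are
  negative binomial with a single shape θ = 30 (variance = μ + μ²/θ).
  Zeros beyond the NB come from an explicit dropout layer, for
  interpretability.
- **Dropout.** Keep probability is `sigmoid(2.0 × (ln λ − 2.5) + shifts)`.
  Two tumor terms enter the logit: a *sample-level* shift (ladder ±0.7 over
  tumors, applied to every cell of the sample, normal cells included) — a
  coherent detection-depth axis that reproduces the small nonzero tumor NMI
  of normal-cell clustering and survives gene down-sampling at any gene
  count, because it aggregates onto a single axis; and a *cancer-only*
  per-(gene,tumor) repertoire term (`Normal(0, 0.8)`) — which genes a
  tumor's cells tend to detect, dispersed over all genes, so binarized data
  still carries tumor identity while any 50 random genes carry almost none.
  The boosted signature/module genes sit ~7 logits above the midpoint, so
  their dropout (and hence score imputation) is negligible by design.
- **CNV blocks.** Optional `(tumor, gene-range, log2 multiplier)` blocks
  multiply expected counts; by default each tumor gains one chromosome
  (×1.5) in the low-index range, away from the special genes. Genes are
  assigned to 22 contiguous chromosome blocks.

Defaults were calibrated once, jointly, against the qualitative contrasts
the analysis is built to show — cancer-cell clustering NMI ≥ 0.5 vs normal
≤ 0.2; standardization removing the identity; binarization retaining it;
score–state Spearman ≥ 0.8 at unit state effect; the 50-gene down-sampling
floor meeting the normal-cell reference — and then frozen; they are stable
across seeds 0–3. With these defaults a 1450 × 5000 cohort simulates in a
few seconds.

What the generator does **not** emulate: UMI vs read-count distinctions,
doublets, fitted-to-real-data parameter realism (Splatter-style), per-gene
dispersion trends (a single NB shape serves all genes; low-abundance noise
is instead dominated by the explicit dropout layer), cell-cycle or other
nuisance covariates, and amplicon/length biases. One visible compositional
consequence: because CPM renormalizes per cell, raising the state genes in
HIGH cells slightly depresses every other gene's CPM, so genome-wide DE
between HIGH and LOW contains a broad low-amplitude LOW-direction component —
a real artifact of compositional normalization, worth remembering when
interpreting DE counts on synthetic data. Passing tests therefore show the
*procedures* are correct and the *contrasts* are achievable under the stated
generative assumptions — not that any particular biological dataset will
reproduce them.

## Numerical choices and degenerate inputs

- QC thresholds use strict `<` ("fewer than") semantics; the gene filter is
  inclusive (`≥ 3` cells).
- `log2(CPM+1)` requires positive per-cell totals; a zero-total cell is an
  error naming the cell.
- Standardization uses sample SD (n−1); zero-SD genes map to 0 to keep the
  matrix shape stable; groups of one cell are errors.
- NMI snaps to exactly 1.0 when within 1e-12 of it (guarding `sqrt(H·H)`
  rounding) and clips to [0,1].
- The exact Mann-Whitney cutover at both groups ≤ 8 balances fidelity and
  cost; constant genes get U = n₁n₂/2, p = 1 without a direction.
- Equal-frequency MI binning deduplicates tied quantile edges; constant genes
  get a zero MI row and a warning.
- The principal curve raises on all-identical points, < 10 cells, or < 2
  dimensions; `max_iter=0` returns the first-PC initialization with
  `converged=False`.
- All pipeline randomness flows from a single root seed, split per stage and
  recorded in the run manifest; identical config + seed give byte-identical
  TSV outputs.

## Problem sizes

The bundled study-condition cohort is 4 tumors × 250 cancer cells,
3 lineages × 150 normal cells, 5000 genes — the scale at which every
full-pipeline property in the test suite is exercised. The down-sampling
experiment runs 6 sizes × 10 replicates; hub recovery uses ten
2-tumor × 200-cell, 1500-gene cohorts with 200-permutation nulls. These
sizes keep the complete test suite within a few minutes on one CPU while
leaving each contrast a comfortable margin.

## Known limitations

- The inertia-ratio cut can return a coarser partition than the label count
  when successive merges remove similar inertia (supersets of tumors still
  score high NMI; on the default cohort the cut finds k = 4 exactly).
- The MI skeleton is undirected and unpruned; "hub" means highest weighted
  degree, not a causal source.
- The lowess-based curve can fail to converge in 50 iterations on strongly
  curved clouds (the flag reports this); the fitted polyline is still usable
  for ordering, which is all downstream stages consume.
- Quartile splits require a non-degenerate distribution (Q1 < Q3).
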