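# gliosig

Signature-driven analysis of single-cell tumor transcriptomes.

When cells from several patients' tumors are clustered together, cancer cells
group first by their **tumor of origin** while normal cells group by lineage —
so unsupervised clustering reveals patient identity, not cell functioning
state. This package implements, as a tested and reusable pipeline, the
analysis strategy that diagnoses and then bypasses that confounder in
glioblastoma (GBM) scRNA-seq:

1. **Diagnosis.** Cluster cells with HCPC (Ward linkage on retained principal
   components, data-driven cut) and quantify how much the clustering reflects
   the tumor label with normalized mutual information,
   `NMI(A,B) = I(A;B) / sqrt(H(A) H(B))`, under a battery of treatments
   (binarization, per-tumor standardization, housekeeping-gene normalization,
   CNV / inter-tumor-DE / overdispersed / most-expressed gene filters) and
   under random down-sampling of gene numbers.
2. **Signature scoring.** Score each cell with the geometric mean of the
   log2(CPM+1) expression of a small tumorigenic transcription-factor
   signature (ARNT2, POU3F2, OLIG2, SOX9, SALL2; zeros imputed to 1) and split
   cells at the score mean (tissues at the extreme quartiles) into
   HIGH/LOW tumorigenic-state groups.
3. **Modules, hubs and ordering.** Find genes overexpressed in the HIGH group
   (Mann-Whitney, Benjamini-Hochberg p < 0.01), keep annotated metabolic genes
   whose expression correlates with the score, build a permutation-thresholded
   mutual-information network over them, rank nodes by (weighted) degree to
   find the hub, and order cells along a principal curve fitted to the
   module-gene embedding, with score overlays along arc-length.

No external data is required: a bundled generator simulates the statistical
structure the analysis assumes — per-tumor identity dispersed as small shifts
across *all* genes, tumor-independent lineage signal in normal cells, a latent
tumorigenic state driving the signature and a hub-centred metabolic module,
negative-binomial counts with cell-specific library sizes, and mean-dependent
dropout carrying sample- and tumor-specific detection structure.

## Worked example

```python
import gliosig as gs

adata = gs.simulate_dataset(gs.SimulationConfig(seed=0))   # 1450 cells x 5000 genes
cells, _ = gs.filter_cells(adata)        # < 90,000 reads or < 1700 genes removed
cells, _ = gs.filter_genes(cells)        # genes detected in >= 3 cells kept
cancer = cells[cells.obs["cell_class"] == "cancer"].copy()
cpm = gs.cpm_log(cancer)

tumors = cancer.obs["tumor"].to_numpy()
clusters = gs.cluster_matrix(cpm)                    # HCPC: PCA + Ward + cut
print(gs.nmi(clusters.labels, tumors).value)         # 1.000  <- tumor-driven
std = gs.standardize_within_group(cpm, tumors)
print(gs.nmi(gs.cluster_matrix(std).labels, tumors).value)   # 0.001 <- removed

signature = gs.Signature("tumorigenic", tuple(gs.signature_genes(cancer)))
scores = gs.score(cpm, signature)
split = gs.split_by_mean(scores)
print((split.labels == "HIGH").sum(), (split.labels == "LOW").sum())  # 514 464
```

The first NMI (1.000) says the clustering reproduces the tumor partition
exactly; after per-tumor standardization it falls to the normal-cell reference
level (about 0.13 on this cohort), showing the tumor identity was carried by
the per-tumor expression structure. The mean split separates 514 HIGH from
464 LOW cells; on this synthetic cohort the score tracks the generative
tumorigenic state with Spearman rho = 0.88.

The numbered scripts under `analysis/` run the full story —
`01_simulate_cohort.py` through `06_principal_curve.py` — each printing its
finding and writing tables under `results/`. The same stages are available as
a CLI (`gliosig simulate|run|score|nmi-battery|downsample|de|network|curve`)
driven by a YAML config; see `gliosig run --help`.

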