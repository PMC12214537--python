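# Methods

This note documents the models and procedures implemented in `flowsc`, the
parameters that matter, what the synthetic data emulate, and the design
choices made where the underlying conventions were genuinely open.

## Data model

UMI counts are held genes × cells in a sparse matrix (`CountDataset`), with
per-cell metadata (flow group, sample/mouse id, optional cell type) and a
per-gene mitochondrial flag derived from the mt-/MT- symbol prefix.
Normalized expression (`ExpressionMatrix`) keeps the same orientation and a
normalization tag. Bulk cohorts are samples × genes frames on log2 scale with
group and optional pairing metadata. Readers/writers cover the Matrix Market
triplet (via `scipy.io`), the MSigDB GMT dialect, and plain TSV for bulk data.

## Preprocessing

* **QC** removes a cell only when detected genes < 300, detected genes > 5000,
  or mitochondrial UMI fraction > 0.10 — strict inequalities, so boundary
  cells (exactly 300 or 5000 genes, exactly 10% mito) are kept. The report
  counts each criterion independently and records that doublet removal and
  batch correction are intentionally skipped stages (single synthetic batch).
* **Normalization** is log CP10K: `ln(1 + 10^4 · count / cell_total)`.
  Regularized-NB normalization is a tool internal we do not reproduce; the
  downstream scores are defined on "expression level" generically, and
  Seurat-style log values keep the risk-tier cutpoints (1 and 2) in their
  conventional range. All-zero cells map to all-zero columns with a warning.
* **HVG selection** ranks genes by dispersion (variance/mean of normalized
  values), ties and zero-mean genes resolved by gene order, so it is
  deterministic.
* **Clustering** standardizes genes, takes the top 20 PCs, builds a 15-NN
  graph and runs Leiden at resolution 0.5 (scanpy; fixed random state). The
  contract is behavioral — any standard community method recovering planted
  types would do; tests assert recovery (ARI ≥ 0.9 on separated types), a
  single cluster on one-type data, and per-seed determinism.
* **Annotation** assigns each cluster the candidate type whose marker set has
  the highest mean normalized expression, with margin < 1e-9 (or all-zero
  expression) mapped to "unassigned".
* **UMI downsampling** draws, per cell, a multivariate hypergeometric sample
  of the target total from the cell's UMIs (sampling without replacement), so
  column sums become exactly equal and counts never exceed the originals. The
  default target is the minimum cell total after QC; cells under the target
  are dropped, not resampled.
* **Cell downsampling** equalizes the two flow groups within each cell type by
  subsampling the larger group; cell types with fewer than 10 cells in either
  group are excluded and reported.

## Marker detection

One-vs-rest two-sided Wilcoxon rank-sum per (gene, cluster) on normalized
values. Groups of ≤ 25 cells per side use the exact null (tie-free data);
larger comparisons use the tie-corrected normal approximation with 0.5
continuity correction (the `wilcox.test` convention). log2FC follows the
Seurat convention `log2((mean expm1 in + 1) / (mean expm1 out + 1))`
(pseudocount 1; the source convention leaves the pseudocount unstated).
Bonferroni correction is applied over all genes × clusters tested; the DEG
flag is adjusted p < 0.05. The top-marker pool for scoring uses raw p < 0.05
sorted by decreasing log2FC (switchable to adjusted p): the DEG rule and the
top-200 rule come from different procedural contexts, and raw-p pooling
matches common FindAllMarkers usage. "BH" adjustment is Benjamini–Hochberg
step-up with the `p.adjust(method="BH")` semantics (delegated to statsmodels,
verified against the step-up formula in tests).

## CVD risk gene enrichment score

Per cell type: top-200 markers ∩ risk gene set; each hit tiered by the mean
log-normalized expression over the scored cells (0 if < 1; 1 if in [1, 2];
2 if > 2); tiers summed. Boundary values 1.0 and 2.0 fall in tier 1 — the
printed rule is ambiguous exactly at 2, and the closed middle interval is the
only reading that makes the three clauses partition the line. "Expression
level" is taken as mean log-CP10K expression, the only scale on which the
1/2 cutpoints are conventional. Group stratification computes the score on
each group's cells with markers from the pooled data (per-group markers
available by flag). The package ships only a small demo risk list; real GWAS
lists are supplied as GMT.

## Transcriptional noise

Exactly the pipeline described in the README: balance cells per group within
type (min 10/group), downsample UMIs to the common minimum, pick invariant
genes, sqrt-transform, distance to the (type, group) centroid; plus pairwise
1 − Spearman over all genes. Decisions worth recording:

* Binning/selection statistics (mean, CV) are computed on all retained cells
  pooled across flow groups, so both groups share one invariant gene set and
  distances are comparable; "within each group" in the procedure is read as
  within each expression bin (the union over retained bins is a single set).
  A per-flow-group selection mode exists behind a flag.
* Bins are equal-size rank bins (`np.array_split`, sizes differ by ≤ 1) over
  genes with nonzero mean; the top and bottom bins are dropped; within each
  retained bin `floor(0.10 · bin_size)` lowest-CV genes are taken, ties by
  gene order.
* Spearman uses average ranks; cells with a constant vector are skipped with
  a warning rather than assigned ρ = 0.
* The per-mouse ratio divides the d-flow sample-averaged mean noise by the
  n-flow one, per cell type; the cell-pooled variant is also reported since
  the averaging level for ratio figures is not standardized.
* Rank-sum tests per cell type on per-cell Euclidean noise, BH across types.

## Signature scores

* **Modulation score**: `(1 + mean modulated) / (1 + mean contractile)` with
  the fixed 7- and 5-gene lists (overridable); genes missing from the matrix
  count as zero-expression entries and are reported. The score is > 0, equals
  1 iff the two list means balance, and is strictly monotone in each list.
* **Rank-AUC score**: per cell, genes ranked by decreasing expression with
  ties broken by fixed gene order; the score is the area under the gene-set
  recovery curve within the top 5% of ranks (the common AUCell default,
  exposed as `top_frac`), normalized to [0, 1]. The deterministic tie rule
  makes a seed unnecessary.
* **Bulk score**: mean per-gene z-score across samples over signature genes
  present (zero-variance genes contribute 0); a mean-rank-percentile variant
  is selectable. Absent genes are dropped with a report; the method name is
  recorded in outputs because the convention is not standardized.
* **Preranked enrichment**: weighted KS running-sum with weight exponent 1;
  p from random same-size gene-label permutations (two-sided on |ES|, add-one
  rule); BH across the tested sets.
* **Group comparisons**: rank-sum (default) or t-test for two groups,
  signed-rank/paired t for paired designs, Kruskal–Wallis beyond two groups;
  significance bands n.s. / * / ** / *** / **** at 0.05 / 0.01 / 0.001 /
  0.0001.

## Synthetic data

`generate_sc_dataset` emulates the two-arm artery design: seven canonical cell
types (endothelial, VSMC, fibroblast, pericyte, macrophage, granulocyte,
T cell) with their canonical markers planted (Pecam1/Vwf, Tagln/Myh11,
Lum/Dcn, Rgs5/Pdgfrb, C1qa/Lyz2, S100a8/S100a9, Cd3g/Trbc2), negative-binomial
counts (gamma–Poisson), lognormal library sizes, and mitochondrial genes
pinned to a fixed fraction of each library. Defaults and rationale:

| parameter | default | meaning |
| --- | --- | --- |
| `cells_per_type_per_group` | 200 | cells per type per arm |
| `n_genes` | 2000 | gene universe (named biology + filler) |
| `baseline_mean` | 2.0 | mean UMI per gene ⇒ ~4000 UMI/cell libraries |
| `dispersion` (θ) | 10 | NB inverse-dispersion; extra-Poisson CV² = 0.1, in the range of typical droplet UMI fits |
| `marker_fold` | 8 | marker enrichment in the owning type |
| `library_cv` | 0.3 | lognormal library-size variation, making UMI downsampling a meaningful stage |
| `mito_fraction` | 0.05 | mito share of each library |
| `noise_inflation` | {endothelial: 0.5} | σ of gene-wise lognormal mean jitter in d-flow cells of that type |
| `modulation_shift` | 0.5 | log-fold up/down shift of modulated/contractile genes in d-flow VSMCs |
| `risk_gene_boost` | {fibroblast: 1.0} | log-fold boost of the risk genes in that type |
| `n_samples_per_group` | 3 | mice per arm (round-robin assignment) |

The noise mechanism multiplies each d-flow cell's mean vector by
`exp(ε − σ²/2)`, ε ~ N(0, σ²) i.i.d. per cell **and per gene**. The jitter is
gene-wise because a scalar per cell only rescales the library and would cancel
exactly under equal-total UMI downsampling; gene-wise jitter raises
within-type dispersion — hence both noise metrics — while the centering keeps
marginal mean profiles unchanged at any σ, so mean-expression contrasts stay
null. Setting σ = 0 (or omitting the type) gives the null configuration.

`generate_bulk_cohort` produces paired two-arm cohorts on log2 scale with a
shared within-pair intercept (SD 0.7), per-sample noise (SD 0.5), and an
additive log2 shift of the signature genes in the affected arm.

**What the generator does not emulate:** empirical depth and gene-count
distributions of real accessions, doublets, batch effects, ambient RNA,
cell-type proportion shifts between arms, or gene–gene correlation beyond the
planted programs. Passing tests therefore demonstrate that the statistics
recover their planted effects under the stated noise model at the stated
sizes — not performance on any particular real dataset.

## Problem sizes and numerical choices

Planted-effect acceptance tests run the default-size study (2800 cells × 2000
genes) across 50 seeds for the noise-power, concordance and risk-ranking
checks; the determinism check uses a reduced study (30 cells/type/group, 500
genes), which exercises every stage identically. Exact-arithmetic oracle
comparisons use |Δ| < 1e-12. Ties everywhere (HVG, top markers, AUC ranking,
invariant-gene CV) break by gene order, making every deterministic stage
reproducible byte-for-byte; every stochastic stage takes an explicit seed
(default 0) that is recorded in the CSV header comments.

## Known limitations

* The clustering stage wraps scanpy's PCA/kNN/Leiden; its labels depend on
  that stack's versions, which is why downstream stages accept any label
  vector and the pipeline driver scores the annotated types directly.
* The one-vs-rest exact rank-sum path applies only to tie-free small groups;
  with ties it falls back to the asymptotic approximation, as R does.
* Permutation p-values for preranked enrichment are granular at 1/(n_perm+1);
  FDR across a single tested set equals its p-value.
* Bulk scoring assumes probes were already collapsed to unique gene symbols
  (`collapse_probes` drops multi-gene and unannotated probes — the latter
  choice is ours; the convention for unannotated probes is usually unstated).
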