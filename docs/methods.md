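# Methods

This note documents the statistical procedures implemented in
`scmosaic`, the conventions chosen where a procedure is conventionally
under-specified, what the synthetic-data generator does and does not
emulate, and the limits of what the test suite demonstrates.

## Quality control and normalization

Stages run in a fixed order: gene filter → cell filter → doublet
removal → mitochondrial-gene removal → log-normalization → scaling.

* **Gene filter.** A gene is retained iff it has a nonzero count in at
  least `min_cells` cells (default 10). The boundary is inclusive:
  detected in exactly 10 cells is kept.
* **Cell filter.** Both per-cell totals and detected-feature numbers
  must lie inside the inclusive `[P_lower, P_upper]` band (defaults
  10th/90th). Percentiles use linear interpolation between order
  statistics (numpy's default, the "type 7" convention). By default a
  cell is removed when *either* metric is out of band (`mode="union"`);
  `mode="intersection"` removes only cells violating both. Both
  percentiles are computed once on the pre-filter distribution, never
  re-estimated after removals.
* **Doublets.** Cells with a supplied doublet score strictly greater
  than 0.5 are removed; a score of exactly 0.5 is retained. The score
  itself is an input — this package does not compute one.
* **Mitochondrial genes.** Symbols with a case-insensitive `mt-` prefix
  are dropped, covering both mouse (`mt-Co1`) and human (`MT-CO1`)
  nomenclature.
* **Log-normalization.** `x = ln(1 + c / C · s)` with scale factor
  `s = 10,000`; zero counts map exactly to zero and a cell's values are
  invariant to sequencing depth. Cells with zero totals are a hard
  error directing the user to filter first.
* **Scaling.** Per-gene z-scores with the sample (n−1) standard
  deviation, clipped to ±10; zero-variance genes map to all-zero rather
  than NaN.
* **Variable genes.** Genes are ranked by the residual of
  log10(variance) above a degree-2 polynomial trend fit on log10(mean)
  over genes with positive mean. This is a deterministic,
  dependency-light surrogate for loess-based standardized variance; it
  agrees with it on which strongly overdispersed genes rank at the top
  but will order mid-table genes differently. Zero-variance genes are
  never selected.

## Differential expression

The per-gene test is the two-sided Wilcoxon rank-sum. When both groups
have ≤ 8 observations the p-value is computed by exhaustive enumeration
of all assignments of the pooled midranks, with
`p = P(|W − E[W]| ≥ |obs − E[W]|)` — correct under ties, where the
classical no-ties exact null is not. Larger groups use the normal
approximation with midrank tie correction and continuity correction;
across random instances at group sizes 5–8 the approximation stays
within 0.02 of the exact value (the continuity-corrected form is the
one that achieves this; without it deviations reach ~0.08).

Genes enter the test only when `max(pct_A, pct_B) ≥ min_pct` and
`|log2FC| ≥ logfc_threshold`; the BH correction is computed over the
genes actually tested, so the multiplicity equals the number of rows in
the output. `pct` is the fraction of cells with normalized expression
> 0. The fold change is computed on de-logged means with a pseudocount:
`log2((mean(expm1 x_A) + 1)/(mean(expm1 x_B) + 1))`.

Cluster markers are one-vs-rest applications of the same test
(defaults `min.pct = 0.25`, log-fold threshold 0.25 for cell types;
0.1/0.5 for finer subclusters); clusters with fewer than 3 cells are
skipped with a warning. Marker-positive gating (e.g. Ccr2⁺) thresholds
at a linear-interpolation percentile of scaled expression and keeps
cells *strictly above* it, so constant expression gates nothing.
Gene-set enrichment is the one-sided upper-tail hypergeometric
`P(X ≥ overlap)`.

## Specificity index and cross-dataset comparison

`S(g, c)` is the ratio of the mean log-normalized expression of gene
g over the cells of cluster c to its mean over all cells. The
cell-fraction-weighted mean of every row is exactly 1 by construction.
The upper bound N (number of clusters) is exact for balanced clusters;
with unbalanced clusters a gene exclusive to a cluster holding fewer
than 1/N of the cells can exceed N — the bound is a property of the
balanced design, not of the estimator. Specificity uses normalized
(not raw, not z-scored) expression: z-scores would break the ratio
interpretation, and raw counts would import depth differences; passing
the raw count matrix computes the index on counts when a partner
dataset was processed that way.

Two datasets are compared by Spearman correlation (midranks) between
all pairs of specificity columns over a shared gene set — by default
the intersection of both datasets' top variable genes, or of one top
set with a plain detected-gene universe when the partner is a bulk
array. Genes missing from either dataset are dropped, never
zero-filled, since a fabricated zero is a fabricated specificity.
Constant columns yield an undefined correlation, reported as missing.
Because Spearman is rank-based, any monotone per-gene transformation
applied to both datasets leaves the correspondence unchanged.

## Regulon activity

* **Rank-AUC.** Per cell, all genes are ranked by decreasing
  expression; ties are broken by one seeded gene-order permutation
  shared across cells, recorded via the seed, so scores are
  deterministic. With window `k = ceil(f · n_genes)` (default
  `f = 0.05`), a target at 1-based rank `j ≤ k` contributes
  `k − j + 1` to the recovery-curve area; the score divides by the
  maximum achievable area `mk − m(m−1)/2`, `m = min(|targets|, k)`,
  giving exactly [0, 1]. The expectation under uniform random ranks is
  `k(k+1) / (2n(k − (m−1)/2))`, which the random-set calibration
  benchmark checks by Monte Carlo.
* **Module score.** Genes are cut into `n_bins = 24` equal-frequency
  bins by dataset-average expression; each signature gene draws
  `n_ctrl = 100` controls from its bin with replacement (seeded); the
  score is mean(signature) − mean(pooled controls) per cell. The score
  is invariant to adding a constant to all genes of a cell. Cell-cycle
  scoring is this same operation with phase gene sets; no dedicated
  code path exists.
* **Differential regulons.** Tested on module scores (activity maps
  use AUC; the differential test follows the module-score
  quantification) with a two-sided Wilcoxon between exactly two
  conditions and BH across regulons. The ledger keeps a regulon iff
  adjusted p < 0.05, the regulon is expressed — mean module score > 0
  in at least one condition (a regulon strongly *down* in one condition
  still passes if expressed in the other; only regulons negative in
  both are dropped) — it contains ≥ 1 DEG, and its DEG fraction is
  ≥ 5% of the regulon size.

A caveat worth knowing: module scores of *null* gene sets acquire a
spurious condition effect when a large fraction of the transcriptome is
differential, because the expression-matched control bins are then
contaminated with truly differential genes. At realistic differential
loads (a few percent of genes) the effect is negligible; the ledger
benchmark uses a 5,000-gene universe with a 4% planted load for this
reason.

## Ligand–receptor statistics

Pairs are ordered ligand→receptor; rows supplied receptor-first (via an
orientation column) are flipped and post-flip duplicates collapsed.
Family filtering keeps pairs whose ligand or receptor symbol starts
with a chemokine prefix (CCL/CCR/CX, case-insensitive). Cross-species
symbol conversion happens strictly upstream through an explicit
ortholog map; the interaction module never renames genes.

The cluster-pair score is the arithmetic mean of the ligand's mean
expression in the sender and the receptor's mean in the receiver. A
pair is "expressed" for a cluster pair when both genes are detected in
at least 10% of the respective cluster's cells; non-expressed pairs
carry no p-value. Significance shuffles cluster labels B times
(default 1,000) and uses the add-one estimator
`p = (1 + #{perm ≥ obs})/(B + 1)`, so p is never 0 and lies on the
grid {1/(B+1), …, 1}.

Genotype-differential pair expression compares *per-cell* pair values
`(ligand + receptor)/2` between groups with the same Wilcoxon + BH
machinery; a cluster-level summary comparison is available behind a
flag, since the per-cell and per-cluster readings answer slightly
different questions and the per-cell one has the cells as honest
observational units.

## Pseudotime profiles

Pseudotime is consumed, never inferred. A gene's profile is its mean
normalized expression in equal-width bins over the pseudotime range
(default 20 bins; the tests use 5 bins for ~45-cell bins at the
reference simulation's size — bin count should scale so each bin holds
enough cells for a stable mean). Empty bins are missing and excluded
pairwise. Cosine similarity is `u·v/(‖u‖‖v‖)`; the permutation test
shuffles the bin order of one profile and is two-sided on |cos|, with
the same add-one estimator. Fewer than 4 usable bins is an error — the
permutation space is too small to resolve anything.

## Synthetic data

Counts are negative binomial with a single shared dispersion
(`variance = μ + μ²/θ`, default θ = 2) — the simplest overdispersed
model; there is no claim of gene-specific dispersion realism. The mean
is a product of a per-gene baseline (optionally log-normal across
genes), multiplicative planted effects (cluster markers, genotype
effects, regulon programs, ligand/receptor boosts), an exponential
pseudotime ramp `exp(a·d·t)` with t uniform on [0, 1] in designated
clusters, and a log-normal library-size factor (σ = 0.3, mean 1).
Doublets are sums of two random cells' counts with scores planted above
0.5; singlets score below 0.5. Mitochondrial genes are simulated under
the `mt-` prefix so the removal rule is exercised.

The reference study configuration is 5 clusters × 2 genotypes × 120
cells over 2,000 genes: 6 markers per cluster at fold 8, 20 genotype
markers at fold 4, one regulon (25 targets, fold 4, genotype-coupled)
plus one null regulon, one exclusive Ccl5→Ccr5 sender/receiver axis at
fold 10, two rising and one falling pseudotime gene (amplitude 2), and
5% doublets. The paired-dataset generator plants 25 shared markers per
corresponding cluster at fold 8 — the size of a typical cell-type
signature — relabels the second dataset's clusters by a seeded
permutation, and samples the two datasets with independent noise.

What the generator does **not** emulate: batch effects, ambient RNA,
gene-specific dispersion, realistic gene-gene correlation beyond the
planted programs, and zero inflation beyond what the NB produces.
Passing tests therefore demonstrate the *statistical machinery* —
calibration, recovery of planted effects, exact agreement with
oracles — not performance on any particular real tissue.

## Numerical conventions

* Seeds: every stochastic operation takes an explicit seed; the
  pipeline refuses a config without one. Seeded `numpy.random.default_rng`
  throughout.
* Permutation p-values are never 0 (add-one estimator).
* Ties: midranks everywhere (Wilcoxon, Spearman); AUC ranking ties are
  broken by a recorded seeded permutation.
* Degenerate inputs fail loudly: empty groups, single clusters,
  constant columns, zero-total cells and mismatched sidecar files are
  errors or explicit missing values, never silent coercions.
* All tabular outputs are TSV with a header and a parameter-hash
  comment line; matrices are MatrixMarket + sidecars; reruns with the
  same config are byte-identical.

## Known limitations

* The variable-gene trend is polynomial, not loess; top-set membership
  can differ from loess-based implementations for borderline genes.
* The specificity upper bound N assumes balanced clusters (above).
* The exact Wilcoxon path enumerates `C(n₁+n₂, n₁)` assignments and is
  reserved for groups of ≤ 8 each.
* The ledger's DEG criteria inherit whatever gating was used to build
  the DE table; with aggressive `min.pct`/log-fold gates a regulon's
  targets may be excluded from testing altogether and the regulon can
  only fail the DEG criteria.
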