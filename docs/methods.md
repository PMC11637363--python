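# Methods

## Problem setting

Given a clustered scRNA-seq dataset (a cells × genes count matrix plus one
cluster label per cell), marker genes are usually found one-vs-all: each
cluster is tested against the pooled remaining cells. When clusters belong
to closely related cell types, this produces overlapping marker lists that
capture the shared lineage signature but separate the related clusters
poorly. In a markers × clusters heatmap ordered block-diagonally this shows
up as *off-diagonal* blocks of high expression.

`markertree` addresses this by jointly deriving a hierarchy over the
clusters and split-specific markers: at each level, clusters are grouped so
that one-vs-all markers for the groups show as little off-diagonal signal
as possible; recursion inside each group yields markers that discriminate
ever finer subtypes.

## Preprocessing

The standard pipeline: cells with fewer than `min_genes_per_cell` detected
genes (default 200) or more than `max_mito_fraction` (default 0.05)
mitochondrial counts (genes with ID prefix `MT-`) are removed; counts are
normalized to `target_sum` (default 1e4) per cell and log1p-transformed
(`lognorm`); each gene is z-scored (`scaled`), zero-variance genes map to 0
rather than NaN so downstream linear algebra stays total, and z-scores are
clipped to ±10. Synthetic data produced by this package's generator carries
no mitochondrial annotation and only a few hundred genes, so examples and
tests run it with `min_genes_per_cell=1, max_mito_fraction=1`.

Highly variable genes (the baseline feature set for evaluation) follow the
classic binned-dispersion recipe: per-gene mean and dispersion
(variance/mean) of de-logged normalized expression, 20 equal-width bins of
log1p(mean), within-bin z-scoring of log dispersion, and selection by
`0.0125 < log1p(mean) < 3` and dispersion z > 0.5. The implementation is
checked in the test suite against both an independent straight-line
reimplementation and scanpy's `highly_variable_genes(flavor="seurat")`.

## Marker finding

For a grouping of clusters, each group is tested against all other in-scope
cells with a two-sided Wilcoxon rank-sum test on `lognorm`. For 12 or fewer
cells in scope the permutation null is enumerated exactly (with midrank
ties); otherwise a tie-corrected normal approximation with continuity
correction is used. Genes must be up-regulated (natural-log fold-change of
de-logged means > 0.25, pseudocount 1e-9) and expressed in at least 10% of
the group's cells. Lists are ranked by ascending Bonferroni-adjusted
p-value (ties: descending fold-change, then gene ID; `rank_by="log_fc"`
switches to fold-change-first, the ordering marker heatmaps usually
display) and truncated to `n_top` per group. `n_top` defaults to 13, which
reproduces a ~118-gene budget over 9 clusters, the scale of a typical PBMC
one-vs-all run.

## The heatmap block score

For groups 1..G with marker sets M_1..M_G, on a scoring layer Y:

    diag_i    = mean of Y over (M_i × cells of group i)
    offdiag_i = max over base clusters c ∉ group i of
                mean of Y over (M_i × cells of cluster c)
    s = (Σ diag_i − k · Σ offdiag_i) / G

with k = 5 by default. Higher s is better: it rewards strong diagonal
blocks and penalizes the worst off-diagonal block per marker set.

Two design choices matter and were settled empirically:

* **Off-diagonal maxima range over base clusters, not merged groups.** If
  the off-diagonal mean were taken over a merged group's pooled cells, a
  strong bleed-over confined to one member cluster would be diluted by the
  other members, and the agglomeration would preferentially merge
  *unrelated* clusters (which dilutes every off-diagonal block) instead of
  related ones. With base-cluster blocks, bleed-over can only be removed by
  absorbing the offending cluster into the group, which is exactly the
  intended behavior.

* **The scoring layer is the z-scored layer clipped to [floor, clip] =
  [0, 2.5].** The ceiling is the usual heatmap display saturation. The
  floor encodes that a block mean measures *presence* of expression:
  without it, merges can look beneficial merely because marker means drop
  below the per-gene baseline (negative z) elsewhere, which again rewards
  merging well-separated clusters. With the floor, merging orthogonal
  clusters strictly lowers the diagonal term without lowering the
  off-diagonal term, so flat structures stay flat. `floor=None` restores
  symmetric ±clip behavior; `layer="lognorm"` scores raw log expression.

## Agglomeration and the divisive hierarchy

Each split is built agglomeratively: starting from singleton groups, all
C(G,2) candidate merges are evaluated — markers re-identified from scratch
for each candidate grouping (memoized per exact partition), then scored —
and the best merge is accepted while it improves s by more than the tie
tolerance (1e-9; candidate ties break toward the smallest index pair).
Agglomeration never goes below two groups, since both the score and the
one-vs-all subroutine are undefined for a single group. The final groups
become the node's children; recursion descends into every child with at
least two member clusters, restricting the dataset to the child's cells but
reusing the globally scaled layer (re-scaling per node would make scores
incomparable across levels and is never hinted at by the construction).
When no merge is ever accepted the tree has depth 1 and its split markers
equal the flat one-vs-all run gene for gene — the degenerate case expected
for datasets of well-separated clusters.

## Assembled feature matrix

Per-split marker heatmaps are concatenated into one cells × features
matrix: features are (split, group, gene) triples in tree pre-order, and
entries for cells whose cluster lies outside a split's scope are set to
exactly 0 (not NaN — the matrix feeds distance-based classifiers). A gene
selected at several splits contributes several features with different
masks. This matrix backs both the assembled heatmap (masked entries drawn
white) and the evaluation harness.

## Evaluation harness

Within-dataset: stratified 70/30 train/test split, Euclidean K-nearest-
neighbor classifier (K = 15 by default; K is not dictated by anything in
the method and is exposed), per-class recall on the test set, and the
unweighted macro mean as the summary ("average accuracy"), so rare cell
types weigh as much as abundant ones.

Cross-dataset mapping: feature genes are chosen on the labeled reference
only (`all`, `hvg_overlap` = intersection of independently selected HVGs,
`flat_markers`, `hier_markers`), intersected with the query's gene
namespace; the classifier is trained on the reference and evaluated per
class on the query. For `hier_markers` the hierarchy and masks are built on
the reference; query cells receive full (unmasked) expression over all
split features because masking requires cluster identity — the very thing
being predicted. No batch correction is applied: robustness to batch
effects is what the comparison measures.

## Synthetic data generator

The generator emulates the hierarchical structure the method exploits:
lineages containing subtypes, with disjoint planted marker blocks per
lineage node and per subtype node. Counts are negative binomial
(gamma–Poisson, var = μ + d·μ²) with gene-wise mean `base_mean ·
exp(Σ effects along the cell's path) · library factor`, library factors
log-normal with a given CV. Defaults — 2 lineages × 2 subtypes, 100 cells
per leaf, 500 genes, 10 markers per node, lineage effect 1.5, subtype
effect 1.0 (log scale), base mean 0.5, dispersion 0.5, library CV 0.25 —
are sized so that lineage markers bleed across sibling subtypes (the
phenomenon under study) while subtype markers remain discriminative.
`orthogonal_spec` produces the opposite regime: single-subtype lineages
whose planted markers are all cluster-exclusive, at 300 cells per cluster
(the scale of the classic 4-cluster pancreas benchmark, where the method
should and does stay flat).

`batch_shift` emulates re-assaying on a shifted platform: a log-normal
gene-wise factor exp(N(0, amplitude)) shared by all cells scales the count
rates, with Poisson resampling to keep counts integral; amplitude 0 is the
identity. The hierarchical-vs-flat mapping comparison uses amplitude 0.5, a
moderate batch effect chosen once for that experiment.

What the generator does **not** model: dropout beyond NB sparsity, doublets,
ambient RNA, per-cell-type library differences, gene–gene correlation
within marker blocks. Passing tests therefore demonstrate that the
algorithm recovers planted hierarchical structure under realistic count
noise — not that it resolves every real tissue.

## Numerical conventions and problem sizes

Score comparisons use an absolute tie tolerance of 1e-9; zero-variance
genes scale to 0; the Wilcoxon normal approximation returns p = 1 when the
pooled sample is constant; all randomness flows from explicit seeds
(`numpy.random.default_rng`). The bundled evaluation scripts run at
desk scale — 400–1,200 cells, 300–500 genes, 20 seeded replicates per
stochastic claim — sizes at which every reported phenomenon is stable
across seeds while a full run completes in well under a minute.

## Known limitations

* The greedy agglomeration optimizes one merge at a time; it can stop at a
  local optimum of s (no global search over partitions is attempted).
* `n_top` is held fixed per group as groups merge, so the total marker
  budget grows with the number of splits; the flat/hierarchical comparison
  reports distinct gene counts so users can match budgets.
* Scores are comparable across levels only because scaling is global; data
  with strong per-lineage library composition differences may warrant
  per-node re-scaling, which is deliberately not the default.
* Cross-dataset mapping assumes a shared gene namespace and identical label
  vocabulary; it does not attempt label harmonization.
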