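# markertree

Hierarchical marker gene selection for clustered scRNA-seq data.

## Why

One-vs-all differential expression — the default way to pick marker genes
for cell clusters — returns overlapping marker lists for closely related
clusters: the genes capture the shared lineage signature (visible as
off-diagonal blocks of high expression in a markers × clusters heatmap)
but barely separate the related clusters from each other. `markertree`
instead builds a hierarchy over the clusters and selects markers per
*split*, so each list is specific to the distinction it has to make:
lineage markers at the top, subtype markers near the leaves.

## Method

For a grouping of the clusters into groups 1..G with one-vs-all
(Wilcoxon rank-sum) marker sets M₁..M_G, the marker heatmap is scored as

    s = (V_diagonal − k · V_off-diagonal) / G,        k = 5

where V_diagonal sums each group's mean marker expression over its own
cells and V_off-diagonal sums, per marker set, the maximum mean over the
base clusters outside the group (expression read from the z-scored layer
clipped to [0, 2.5]). Each split of the hierarchy is found
agglomeratively: all pairwise merges are evaluated — markers re-identified
for every candidate grouping — and the best merge is accepted while it
increases s; divisive recursion into the final groups, with the data
restricted to each group's cells, yields the tree. Per-split marker
submatrices are concatenated into an assembled feature matrix whose
entries are zeroed for cells outside each split's scope; that matrix
drives UMAP visualization and KNN-based evaluation, both within a dataset
(stratified 70/30, macro-averaged per-class accuracy) and across datasets
(train on a labeled reference, predict a batch-shifted query).

On data whose clusters are all well separated, no merge improves s and
the "hierarchy" collapses to the flat one-vs-all structure.

## Worked example

The package ships a seeded generator of hierarchically structured counts
(2 lineages × 2 subtypes by default), so the whole pipeline runs without
downloads:

```sh
markertree simulate --out sim --seed 1 --cells-per-leaf 100 --n-genes 500
markertree preprocess --counts sim --labels sim/labels.tsv \
    --out ds.h5ad --qc-report qc.tsv --min-genes 1 --max-mito 1.0
markertree hierarchy --data ds.h5ad --out-dir hier
markertree assemble --data ds.h5ad --hierarchy-dir hier \
    --out-prefix assembled --heatmap heatmap.png
markertree evaluate --data ds.h5ad --selector hier_markers --out-prefix eval_hier --seed 0
markertree evaluate --data ds.h5ad --selector flat_markers --out-prefix eval_flat --seed 0
```

prints

```
wrote 400 cells x 500 genes to sim
kept 400/400 cells; wrote ds.h5ad
hierarchy depth 2, 3 splits, 71 distinct marker genes -> hier
400 cells x 78 features (10400 masked entries) -> assembled.mtx
hier_markers: average accuracy 0.842
flat_markers: average accuracy 0.808
```

and `hier/hierarchy.nwk` contains `((L1.a,L1.b),(L2.a,L2.b));` — the
planted two-level structure: the root split separates the two lineages,
each lineage then splits into its subtypes. The assembled matrix has 78
features (13 markers × 2 groups at the root split, plus 13 × 2 at each of
the two lineage-internal splits); its 10,400 masked entries are the cells
outside each lineage split's scope (200 cells × 26 features × 2 splits),
drawn white in `heatmap.png`. The macro-averaged KNN accuracy of the
masked hierarchical features (0.842) beats the flat one-vs-all markers
(0.808) on the same data and seed.

The same API is available as a library:

```python
from markertree import HierSpec, generate, preprocess, build_hierarchy
from markertree.dataset import QCConfig

ds, truth, planted = generate(HierSpec(seed=1))
pp = preprocess(ds, QCConfig(min_genes_per_cell=1, max_mito_fraction=1.0))
root = build_hierarchy(pp)          # HierarchyNode
print(root.to_newick())             # ((L1.a,L1.b),(L2.a,L2.b));
```

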