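"""Assembled zero-masked feature matrix and its heatmap rendering.

The per-split marker heatmaps are concatenated into a single cells x
features matrix: features are (split, group, gene) triples in tree pre-order
(groups in grouping order, genes in marker rank order), and entries are set
to exactly 0 for cells whose base cluster is outside the split's scope.
That masked matrix is the feature space used for UMAP visualization and
KNN classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .dataset import ExpressionDataset
from .errors import MarkerTreeError, ValidationError
from .hierarchy import HierarchyNode


@dataclass
class AssembledFeatureMatrix:
    """Cells x concatenated split-marker features with structural zeros.

    ``feature_meta`` has one row per feature: (split_id, group, gene).
    ``in_scope`` marks entries that belong to a split's scope; everything
    else is exactly 0 in ``values``.
    """

    values: np.ndarray
    feature_meta: pd.DataFrame
    cell_ids: list[str]
    split_order: list[str]
    in_scope: np.ndarray

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def n_masked(self) -> int:
        return int((~self.in_scope).sum())

    def write(self, prefix) -> None:
        """Write values as MTX plus a feature-metadata TSV."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(
            str(prefix.with_suffix(".mtx")), scipy.sparse.csr_matrix(self.values)
        )
        self.feature_meta.to_csv(
            prefix.with_suffix(".features.tsv"), sep="\t", index=False
        )


def assemble_features(
    ds: ExpressionDataset, root: HierarchyNode, layer: str = "scaled"
) -> AssembledFeatureMatrix:
    """Concatenate per-split marker submatrices with zero masking.

    A gene selected at several splits yields several features (their masks
    differ).  Raises if no split carries any marker gene.
    """
    M = ds.layer(layer)
    gene_pos = {g: i for i, g in enumerate(ds.gene_ids)}
    splits = root.internal_nodes()
    blocks: list[np.ndarray] = []
    scope_cols: list[np.ndarray] = []
    meta_rows: list[tuple[str, str, str]] = []
    split_order: list[str] = []
    for node in splits:
        mt = node.split_markers
        if mt is None:
            raise ValidationError(f"split {node.node_id} has no marker table")
        genes: list[tuple[str, str]] = []
        for grp in mt.group_order:
            genes.extend((grp, g) for g in mt.genes(grp))
        if not genes:
            continue
        split_order.append(node.node_id)
        scope_mask = ds.cells_in_clusters(node.members)
        cols = [gene_pos[g] for _, g in genes]
        block = np.where(scope_mask[:, None], M[:, cols], 0.0)
        blocks.append(block)
        scope_cols.append(np.repeat(scope_mask[:, None], len(cols), axis=1))
        meta_rows.extend((node.node_id, grp, g) for grp, g in genes)
    if not blocks:
        raise MarkerTreeError("every split has an empty marker table")
    return AssembledFeatureMatrix(
        values=np.concatenate(blocks, axis=1),
        feature_meta=pd.DataFrame(meta_rows, columns=["split_id", "group", "gene"]),
        cell_ids=list(ds.cell_ids),
        split_order=split_order,
        in_scope=np.concatenate(scope_cols, axis=1),
    )


def render_heatmap(
    am: AssembledFeatureMatrix,
    ds: ExpressionDataset,
    out,
    vmax: float = 2.5,
) -> None:
    """Render the assembled heatmap: features on rows grouped into one
    horizontal section per split, cells on columns grouped by base cluster,
    masked entries shown white."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if am.n_features == 0:
        raise ValidationError("assembled matrix is empty")
    order = np.argsort(np.asarray(ds.cluster_labels, dtype=str), kind="stable")
    data = am.values[order].T  # features x cells
    mask = ~am.in_scope[order].T
    shown = np.ma.masked_array(np.clip(data, -vmax, vmax), mask=mask)

    fig, ax = plt.subplots(
        figsize=(max(4.0, data.shape[1] / 60), max(3.0, data.shape[0] / 12))
    )
    cmap = plt.get_cmap("coolwarm").copy()
    cmap.set_bad("white")
    ax.imshow(shown, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)

    # horizontal section boundaries between splits
    sizes = am.feature_meta.groupby("split_id", sort=False).size()
    edge = 0
    for split_id, size in sizes.items():
        edge += size
        ax.axhline(edge - 0.5, color="black", lw=0.6)
        ax.text(
            -0.5,
            edge - size / 2,
            str(split_id),
            ha="right",
            va="center",
            fontsize=6,
        )
    # vertical boundaries between base clusters
    labs = np.asarray(ds.cluster_labels, dtype=str)[order]
    changes = np.flatnonzero(labs[1:] != labs[:-1])
    for c in changes:
        ax.axvline(c + 0.5, color="black", lw=0.4)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_xlabel("cells (grouped by cluster)")
    ax.set_ylabel("split marker genes")
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)


def export_umap(
    matrix: np.ndarray,
    labels,
    seed: int = 0,
    cell_ids=None,
    out=None,
    n_neighbors: int = 15,
) -> pd.DataFrame:
    """Embed cells in 2-D with UMAP; deterministic under a fixed seed.

    Returns a table (cell_id, x, y, label), optionally written as TSV.
    """
    matrix = np.asarray(matrix)
    if matrix.shape[0] < 10:
        raise ValidationError("UMAP export needs at least 10 cells")
    import umap

    try:
        emb = umap.UMAP(
            n_components=2, random_state=seed, n_neighbors=n_neighbors
        ).fit_transform(matrix)
    except Exception as exc:
        raise MarkerTreeError(f"UMAP embedding failed: {exc}") from exc
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(matrix.shape[0])]
    df = pd.DataFrame(
        {"cell_id": cell_ids, "x": emb[:, 0], "y": emb[:, 1], "label": list(labels)}
    )
    if out is not None:
        df.to_csv(out, sep="\t", index=False)
    return df
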