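"""Core in-memory container for clustered expression data.

An :class:`ExpressionDataset` holds a cells x genes raw count matrix plus the
two derived layers the rest of the package reads: ``lognorm`` (library-size
normalized, log1p) and ``scaled`` (per-gene z-scores of lognorm, optionally
clipped).  Cluster labels are per-cell categorical strings; clustering itself
is outside the scope of this package — labels are an input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class QCConfig:
    """Quality-control and normalization parameters.

    min_genes_per_cell : cells detecting fewer genes are removed (default 200).
    max_mito_fraction  : cells whose mitochondrial count fraction exceeds this
                         are removed (default 0.05).
    mito_prefix        : gene-ID prefix identifying mitochondrial genes.
    target_sum         : per-cell library size after normalization (1e4).
    clip_value         : symmetric clip for the scaled layer; None disables.
    """

    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.05
    mito_prefix: str = "MT-"
    target_sum: float = 1e4
    clip_value: Optional[float] = 10.0

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0:
            raise ValidationError("min_genes_per_cell must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValidationError("max_mito_fraction must be in [0, 1]")
        if self.target_sum <= 0:
            raise ValidationError("target_sum must be positive")
        if self.clip_value is not None and self.clip_value <= 0:
            raise ValidationError("clip_value must be positive or None")


@dataclass
class ExpressionDataset:
    """Counts plus derived layers, cell/gene identifiers and cluster labels.

    All layers share shape ``(n_cells, n_genes)`` and row/column order.
    ``cluster_labels`` is None until :func:`markertree.io.attach_labels` is
    called; every attached label must cover >= 2 cells.
    """

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    lognorm: Optional[np.ndarray] = None
    scaled: Optional[np.ndarray] = None
    cluster_labels: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        for layer_name in ("lognorm", "scaled"):
            layer = getattr(self, layer_name)
            if layer is not None and layer.shape != self.counts.shape:
                raise ValidationError(f"{layer_name} shape mismatch with counts")
        if self.cluster_labels is not None:
            self.cluster_labels = np.asarray(self.cluster_labels, dtype=object)
            if len(self.cluster_labels) != n_cells:
                raise ValidationError("one cluster label required per cell")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cluster_names(self) -> list[str]:
        """Distinct cluster labels in lexicographic order."""
        if self.cluster_labels is None:
            raise ValidationError("dataset has no cluster labels attached")
        return sorted(set(self.cluster_labels))

    def layer(self, name: str) -> np.ndarray:
        """Return a named layer ('counts', 'lognorm' or 'scaled')."""
        if name not in ("counts", "lognorm", "scaled"):
            raise ValidationError(f"unknown layer {name!r}")
        arr = getattr(self, name)
        if arr is None:
            raise ValidationError(f"layer {name!r} has not been computed")
        return arr

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)

    # -- subsetting --------------------------------------------------------

    def subset_cells(self, mask_or_idx) -> "ExpressionDataset":
        """Row-subset every layer (and labels) by a boolean mask or index."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            counts=self.counts[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            lognorm=None if self.lognorm is None else self.lognorm[idx],
            scaled=None if self.scaled is None else self.scaled[idx],
            cluster_labels=None
            if self.cluster_labels is None
            else self.cluster_labels[idx],
        )

    def cells_in_clusters(self, clusters) -> np.ndarray:
        """Boolean mask of cells whose label is in `clusters`."""
        if self.cluster_labels is None:
            raise ValidationError("dataset has no cluster labels attached")
        members = set(clusters)
        return np.fromiter(
            (lab in members for lab in self.cluster_labels),
            dtype=bool,
            count=self.n_cells,
        )

    def validate_labels(self) -> None:
        """Check the >=2-cells-per-cluster invariant."""
        if self.cluster_labels is None:
            raise ValidationError("dataset has no cluster labels attached")
        counts = pd.Series(self.cluster_labels).value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValidationError(
                "clusters with fewer than 2 cells: " + ", ".join(map(str, small.index))
            )
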