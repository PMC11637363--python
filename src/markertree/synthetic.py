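"""Seeded generator of hierarchically structured scRNA-seq-like counts.

Cells are organized as lineages -> subtypes.  Each lineage node and each
subtype node owns a disjoint block of planted marker genes whose negative-
binomial mean is multiplied by ``exp(effect)`` for cells under that node,
emulating the shared-lineage-signature-plus-subtype-marker structure that
makes closely related clusters bleed into each other's one-vs-all marker
heatmaps.  Per-cell library sizes are log-normal.  Everything is
deterministic under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from . import io as mtio
from .dataset import ExpressionDataset
from .errors import SimSpecError


@dataclass
class HierSpec:
    """Specification of a planted two-level hierarchy.

    tree             : lineage name -> {subtype name -> n cells}; subtype
                       names must be globally unique (they become the base
                       cluster labels).
    n_genes          : total genes.
    markers_per_node : planted markers for every lineage and subtype node.
    lineage_effect   : log-scale mean shift for lineage markers (default 1.5).
    subtype_effect   : log-scale mean shift for subtype markers (default 1.0).
    base_mean        : baseline NB mean per gene (default 0.5).
    dispersion       : NB dispersion d, var = mu + d * mu^2 (default 0.5).
    library_size_cv  : coefficient of variation of per-cell library factors.
    """

    tree: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {
            "L1": {"L1.a": 100, "L1.b": 100},
            "L2": {"L2.a": 100, "L2.b": 100},
        }
    )
    n_genes: int = 500
    markers_per_node: int = 10
    lineage_effect: float = 1.5
    subtype_effect: float = 1.0
    base_mean: float = 0.5
    dispersion: float = 0.5
    library_size_cv: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        subtypes = [s for subs in self.tree.values() for s in subs]
        if len(set(subtypes)) != len(subtypes):
            raise SimSpecError("subtype names must be globally unique")
        clash = set(subtypes) & set(self.tree)
        if clash:
            raise SimSpecError(
                f"names used for both a lineage and a subtype: {sorted(clash)}"
            )
        for subs in self.tree.values():
            for name, n in subs.items():
                if n < 2:
                    raise SimSpecError(f"leaf {name!r} needs >= 2 cells")
        if self.lineage_effect < 0 or self.subtype_effect < 0:
            raise SimSpecError("effects must be >= 0")
        if self.base_mean <= 0 or self.dispersion < 0:
            raise SimSpecError("base_mean must be > 0 and dispersion >= 0")
        n_nodes = len(self.tree) + len(subtypes)
        if self.markers_per_node * n_nodes > self.n_genes:
            raise SimSpecError(
                f"marker budget {self.markers_per_node} x {n_nodes} nodes "
                f"exceeds {self.n_genes} genes"
            )


def orthogonal_spec(n_clusters: int = 4, cells_per_cluster: int = 300, **kw) -> HierSpec:
    """A flat design: every cluster is its own single-subtype lineage, so
    all planted markers (lineage and subtype blocks alike) are exclusive to
    one cluster — no shared signatures."""
    tree = {
        f"C{i}-lineage": {f"C{i}": cells_per_cluster}
        for i in range(1, n_clusters + 1)
    }
    return HierSpec(tree=tree, **kw)


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, d: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson; d=0 degenerates to Poisson."""
    if d == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / d, scale=mu * d)
    return rng.poisson(lam)


def generate(spec: HierSpec) -> tuple[ExpressionDataset, dict, dict]:
    """Draw a counts dataset with true leaf labels.

    Returns ``(dataset, truth, marker_map)`` where ``truth`` records the
    lineage -> subtypes tree and ``marker_map`` maps each node name to its
    planted marker gene ids.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"g{i:04d}" for i in range(spec.n_genes)]

    # consecutive disjoint marker blocks, lineages first then subtypes
    marker_map: dict[str, list[str]] = {}
    cursor = 0
    node_names = list(spec.tree) + [s for subs in spec.tree.values() for s in subs]
    for name in node_names:
        marker_map[name] = gene_ids[cursor : cursor + spec.markers_per_node]
        cursor += spec.markers_per_node

    cells: list[str] = []
    labels: list[str] = []
    log_shift_rows: list[np.ndarray] = []
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for lineage, subs in spec.tree.items():
        for subtype, n in subs.items():
            shift = np.zeros(spec.n_genes)
            for node, eff in ((lineage, spec.lineage_effect),
                              (subtype, spec.subtype_effect)):
                for g in marker_map[node]:
                    shift[gene_pos[g]] += eff
            for _ in range(n):
                cells.append(f"c{len(cells):05d}")
                labels.append(subtype)
                log_shift_rows.append(shift)
    n_cells = len(cells)

    sigma = np.sqrt(np.log1p(spec.library_size_cv**2))
    lib = np.exp(rng.normal(-(sigma**2) / 2, sigma, size=n_cells))
    mu = spec.base_mean * np.exp(np.vstack(log_shift_rows)) * lib[:, None]
    counts = _nb_sample(rng, mu, spec.dispersion)

    ds = ExpressionDataset(
        counts=counts.astype(np.int64),
        cell_ids=cells,
        gene_ids=list(gene_ids),
        cluster_labels=np.array(labels, dtype=object),
    )
    truth = {lineage: sorted(subs) for lineage, subs in spec.tree.items()}
    return ds, truth, marker_map


def batch_shift(
    ds: ExpressionDataset, amplitude: float, seed: int = 0
) -> ExpressionDataset:
    """Apply a shared gene-wise multiplicative batch factor to the counts.

    Each gene's counts are rescaled by a log-normal factor exp(N(0,
    amplitude)) common to all cells, with Poisson resampling to keep counts
    integral — mimicking re-assaying the same cells on a shifted platform.
    Labels are preserved; derived layers are dropped (re-preprocess the
    result).  ``amplitude == 0`` returns an exact copy.
    """
    if amplitude < 0:
        raise SimSpecError("amplitude must be >= 0")
    if amplitude == 0:
        return replace(ds, lognorm=None, scaled=None)
    rng = np.random.default_rng(seed)
    factors = np.exp(rng.normal(0.0, amplitude, size=ds.n_genes))
    shifted = rng.poisson(ds.counts * factors[None, :])
    return replace(
        ds, counts=shifted.astype(np.int64), lognorm=None, scaled=None
    )


def write_dataset(
    ds: ExpressionDataset, truth: dict, marker_map: dict, directory
) -> None:
    """Write the standard 10x MTX triplet, labels TSV and ground-truth JSON."""
    directory = Path(directory)
    mtio.write_mtx_dir(ds, directory)
    mtio.write_labels_tsv(ds, directory / "labels.tsv")
    mtio.write_truth_json(
        {"tree": truth, "markers": marker_map}, directory / "truth.json"
    )
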