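import numpy as np
import pytest

from markertree import ExpressionDataset, HierSpec, generate, preprocess
from markertree.dataset import QCConfig


@pytest.fixture
def synth_qc() -> QCConfig:
    """QC settings sized for the synthetic generator (few hundred genes,
    no mitochondrial annotation)."""
    return QCConfig(min_genes_per_cell=1, max_mito_fraction=1.0)


SYNTH_QC = QCConfig(min_genes_per_cell=1, max_mito_fraction=1.0)


@pytest.fixture(scope="session")
def planted():
    """A preprocessed 2 lineages x 2 subtypes dataset with ground truth."""
    ds, truth, marker_map = generate(HierSpec(seed=1))
    return preprocess(ds, SYNTH_QC), truth, marker_map


def make_dataset(counts, labels=None, lognorm=None, scaled=None):
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    return ExpressionDataset(
        counts=counts,
        cell_ids=[f"c{i}" for i in range(n_cells)],
        gene_ids=[f"g{i}" for i in range(n_genes)],
        lognorm=None if lognorm is None else np.asarray(lognorm, dtype=float),
        scaled=None if scaled is None else np.asarray(scaled, dtype=float),
        cluster_labels=None if labels is None else np.array(labels, dtype=object),
    )


def topology_signature(node):
    """Nested frozensets describing the tree shape over leaf labels."""
    if node.is_leaf:
        return next(iter(node.members))
    return frozenset(topology_signature(c) for c in node.children)


def expected_two_level(truth):
    """Signature of a correct lineages-then-subtypes tree."""
    return frozenset(frozenset(subs) for subs in truth.values())
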