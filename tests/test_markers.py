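import itertools
from math import factorial

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from markertree import (
    ClusterGrouping,
    one_vs_all_markers,
    preprocess,
    wilcoxon_rank_sum,
)
from markertree.dataset import QCConfig
from markertree.errors import DegenerateGroupError, ValidationError
from markertree.markers import MarkerConfig, MarkerTable

from conftest import make_dataset

NOQC = QCConfig(min_genes_per_cell=0, max_mito_fraction=1.0)


def enumeration_oracle(x, y):
    """Two-sided exact p by explicit enumeration of all permutations of
    group assignments (independent of the implementation's subset walk)."""
    pooled = list(x) + list(y)
    n, n1 = len(pooled), len(x)
    # midranks by counting, no library call
    ranks = []
    for v in pooled:
        less = sum(1 for w in pooled if w < v)
        equal = sum(1 for w in pooled if w == v)
        ranks.append(less + (equal + 1) / 2.0)
    w_obs = sum(ranks[:n1])
    mu = n1 * (n + 1) / 2.0
    hits = 0
    for perm in itertools.permutations(range(n)):
        w = sum(ranks[i] for i in perm[:n1])
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / factorial(n)


def test_exact_p_one_third():
    w, p = wilcoxon_rank_sum([1, 2], [3, 4], mode="exact")
    assert w == 3.0
    assert p == pytest.approx(1 / 3)


def test_identical_multisets_give_p_one():
    w, p = wilcoxon_rank_sum([1.0, 2.0], [2.0, 1.0], mode="exact")
    assert p == 1.0
    assert w == pytest.approx(2 * (4 + 1) / 2.0)  # statistic at its null mean


def test_all_constant_p_one():
    _, p = wilcoxon_rank_sum([3, 3, 3], [3, 3], mode="normal")
    assert p == 1.0


@given(
    x=st.lists(st.integers(0, 3), min_size=1, max_size=5),
    y=st.lists(st.integers(0, 3), min_size=1, max_size=5),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_two_sided_p_symmetric_in_samples(x, y):
    _, p_xy = wilcoxon_rank_sum(x, y, mode="exact")
    _, p_yx = wilcoxon_rank_sum(y, x, mode="exact")
    assert p_xy == pytest.approx(p_yx, abs=1e-12)


def test_exact_mode_matches_enumeration_oracle_all_small_layouts():
    rng = np.random.default_rng(11)
    for n_total in range(2, 9):
        for n1 in range(1, n_total):
            for alphabet in ([0, 1, 2], None):  # heavy ties and continuous
                if alphabet is not None:
                    vals = rng.choice(alphabet, size=n_total)
                else:
                    vals = rng.normal(size=n_total)
                x, y = vals[:n1], vals[n1:]
                _, p = wilcoxon_rank_sum(x, y, mode="exact")
                assert p == pytest.approx(enumeration_oracle(x, y), abs=1e-12)


def test_normal_mode_close_to_scipy_and_exact():
    rng = np.random.default_rng(5)
    for _ in range(20):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        _, p_exact = wilcoxon_rank_sum(x, y, mode="exact")
        _, p_norm = wilcoxon_rank_sum(x, y, mode="normal")
        assert p_norm == pytest.approx(p_exact, abs=0.02)
        p_scipy = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert p_norm == pytest.approx(p_scipy, abs=1e-9)


def test_empty_sample_rejected():
    with pytest.raises(ValidationError):
        wilcoxon_rank_sum([], [1, 2])


# -- one-vs-all ------------------------------------------------------------


def _two_group_dataset(rng, n_per=30, n_genes=8, marker=0, shift=5):
    counts = rng.poisson(2.0, size=(2 * n_per, n_genes))
    counts[:n_per, marker] += shift
    labels = ["A"] * n_per + ["B"] * n_per
    return preprocess(make_dataset(counts, labels=labels), NOQC)


def test_perfectly_separating_gene_is_rank_one():
    rng = np.random.default_rng(3)
    counts = rng.poisson(2.0, size=(20, 6))
    counts[:, 2] = 0
    counts[:10, 2] = 50
    ds = preprocess(make_dataset(counts, labels=["A"] * 10 + ["B"] * 10), NOQC)
    mt = one_vs_all_markers(ds, ClusterGrouping.singletons(["A", "B"]))
    assert mt.genes("A")[0] == "g2"


def test_null_identical_distributions_empty_tables():
    rng = np.random.default_rng(0)
    counts = rng.poisson(3.0, size=(400, 30))
    ds = preprocess(
        make_dataset(counts, labels=["A"] * 200 + ["B"] * 200), NOQC
    )
    mt = one_vs_all_markers(ds, ClusterGrouping.singletons(["A", "B"]))
    assert len(mt.table) == 0
    assert mt.genes("A") == [] and mt.genes("B") == []


def test_small_sample_p_matches_brute_force_rank_enumeration():
    # 3 vs 3 cells, one informative gene: the exact two-sided p must equal
    # brute-force enumeration over all C(6,3)=20 rank assignments
    counts = np.array([[5], [6], [7], [1], [2], [3]])
    ds = make_dataset(counts, labels=["A"] * 3 + ["B"] * 3)
    ds.lognorm = counts.astype(float)  # direct values; no renormalization
    mt = one_vs_all_markers(
        ds,
        ClusterGrouping.singletons(["A", "B"]),
        MarkerConfig(n_top=5, lfc_min=0.0, pct_min=0.0),
    )
    row = mt.table[(mt.table["group"] == "A") & (mt.table["gene"] == "g0")]
    expected = enumeration_oracle([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
    assert row["p"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_markers_invariant_to_cell_permutation():
    rng = np.random.default_rng(9)
    ds = _two_group_dataset(rng)
    mt = one_vs_all_markers(ds, ClusterGrouping.singletons(["A", "B"]))
    perm = rng.permutation(ds.n_cells)
    shuffled = ds.subset_cells(perm)
    mt2 = one_vs_all_markers(shuffled, ClusterGrouping.singletons(["A", "B"]))
    assert mt.gene_lists() == mt2.gene_lists()


def test_only_upregulated_genes_listed(planted):
    pp, _, _ = planted
    mt = one_vs_all_markers(pp, ClusterGrouping.singletons(pp.cluster_names))
    assert (mt.table["log_fc"] > 0.25).all()
    assert (mt.table["pct_in"] >= 0.1).all()
    assert (mt.table["p_adj"] >= mt.table["p"] - 1e-15).all()


def test_degenerate_group_rejected():
    ds = make_dataset(np.ones((3, 2), dtype=int))
    ds.cluster_labels = np.array(["A", "B", "B"], dtype=object)
    ds.lognorm = ds.counts.astype(float)
    with pytest.raises(DegenerateGroupError):
        one_vs_all_markers(ds, ClusterGrouping.singletons(["A", "B"]))


def test_marker_table_tsv_roundtrip(tmp_path, planted):
    pp, _, _ = planted
    mt = one_vs_all_markers(pp, ClusterGrouping.singletons(pp.cluster_names))
    path = tmp_path / "markers.tsv"
    mt.write_tsv(path, split_id="flat")
    back = MarkerTable.read_tsv(path)
    assert back.gene_lists() == mt.gene_lists()
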