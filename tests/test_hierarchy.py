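import json

import numpy as np
import pytest

from markertree import (
    ClusterGrouping,
    HierSpec,
    agglomerate,
    best_merge_step,
    build_hierarchy,
    generate,
    heatmap_score,
    one_vs_all_markers,
    orthogonal_spec,
    preprocess,
    score_after_merge,
)
from markertree.dataset import QCConfig
from markertree.errors import ValidationError
from markertree.hierarchy import ScoringConfig, _NodeCache
from markertree.markers import MarkerConfig, MarkerTable

from conftest import SYNTH_QC, expected_two_level, make_dataset, topology_signature


def brute_force_score(layer, labels, grouping, marker_lists, gene_ids, k):
    """Materialize the full heatmap and average blocks with explicit loops.

    Diagonal blocks are per group; the off-diagonal maximum is taken over
    the base clusters outside each group.
    """
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    diag, off = [], []
    for gi, group in enumerate(grouping.groups):
        genes = [gene_pos[g] for g in marker_lists[grouping.group_label(gi)]]
        if not genes:
            diag.append(0.0)
            off.append(0.0)
            continue
        own = [
            layer[i, j]
            for i in range(len(labels))
            if labels[i] in group
            for j in genes
        ]
        diag.append(sum(own) / len(own))
        maxima = []
        for cluster in sorted(grouping.scope):
            if cluster in group:
                continue
            vals = [
                layer[i, j]
                for i in range(len(labels))
                if labels[i] == cluster
                for j in genes
            ]
            maxima.append(sum(vals) / len(vals))
        off.append(max(maxima))
    g = grouping.n_groups
    return (sum(diag) - k * sum(off)) / g


def _layer_dataset(values, labels):
    ds = make_dataset(np.zeros_like(np.asarray(values), dtype=int), labels=labels)
    ds.lognorm = np.asarray(values, dtype=float)
    ds.scaled = np.asarray(values, dtype=float)
    return ds


def test_hand_computed_score_antidiagonal():
    # g0 high in cluster A cells, g1 high in cluster B cells
    values = [[1, -1], [1, -1], [-1, 1], [-1, 1]]
    ds = _layer_dataset(values, ["A", "A", "B", "B"])
    grouping = ClusterGrouping.singletons(["A", "B"])
    markers = MarkerTable.from_gene_lists({"A": ["g0"], "B": ["g1"]})
    rep = heatmap_score(ds, grouping, markers, ScoringConfig(k=5, clip=None, floor=None))
    assert rep.per_group_diag == [1.0, 1.0]
    assert rep.per_group_max_offdiag == [-1.0, -1.0]
    assert rep.s == pytest.approx((2 - 5 * (-2)) / 2)  # = 6


def test_hand_computed_score_uniform_heatmap():
    values = np.ones((4, 2))
    ds = _layer_dataset(values, ["A", "A", "B", "B"])
    grouping = ClusterGrouping.singletons(["A", "B"])
    markers = MarkerTable.from_gene_lists({"A": ["g0"], "B": ["g1"]})
    rep = heatmap_score(ds, grouping, markers, ScoringConfig(k=5, clip=None, floor=None))
    assert rep.v_diagonal == pytest.approx(2.0)
    assert rep.v_off_diagonal == pytest.approx(2.0)
    assert rep.s == pytest.approx(-4.0)


def test_empty_marker_list_contributes_zero():
    values = [[1, -1], [1, -1], [-1, 1], [-1, 1]]
    ds = _layer_dataset(values, ["A", "A", "B", "B"])
    grouping = ClusterGrouping.singletons(["A", "B"])
    markers = MarkerTable.from_gene_lists({"A": ["g0"], "B": []})
    rep = heatmap_score(ds, grouping, markers, ScoringConfig(k=5, clip=None, floor=None))
    assert rep.per_group_diag == [1.0, 0.0]
    assert rep.per_group_max_offdiag == [-1.0, 0.0]


def test_single_group_score_rejected():
    ds = _layer_dataset(np.ones((4, 2)), ["A", "A", "A", "A"])
    grouping = ClusterGrouping((frozenset(["A"]),))
    markers = MarkerTable.from_gene_lists({"A": ["g0"]})
    with pytest.raises(ValidationError):
        heatmap_score(ds, grouping, markers)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_score_matches_brute_force_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    n_groups = rng.integers(2, 7)
    clusters = [f"K{i}" for i in range(n_groups * 2)]
    labels = list(rng.choice(clusters, size=40))
    # ensure every cluster occurs
    labels[: len(clusters)] = clusters
    values = rng.normal(size=(40, 30))
    gene_ids = [f"g{j}" for j in range(30)]
    ds = _layer_dataset(values, labels)
    # random partition of clusters into n_groups groups
    assignment = rng.integers(0, n_groups, size=len(clusters))
    assignment[:n_groups] = np.arange(n_groups)
    groups = [
        frozenset(c for c, a in zip(clusters, assignment) if a == gi)
        for gi in range(n_groups)
    ]
    grouping = ClusterGrouping(tuple(groups))
    lists = {}
    for gi in range(grouping.n_groups):
        chosen = rng.choice(30, size=rng.integers(1, 6), replace=False)
        lists[grouping.group_label(gi)] = [gene_ids[j] for j in chosen]
    markers = MarkerTable.from_gene_lists(lists, grouping.group_labels)
    rep = heatmap_score(ds, grouping, markers, ScoringConfig(k=5, clip=None, floor=None))
    expected = brute_force_score(values, labels, grouping, lists, gene_ids, k=5)
    assert rep.s == pytest.approx(expected, rel=1e-12, abs=1e-12)


# -- merge step ------------------------------------------------------------


@pytest.fixture(scope="module")
def shared_signature_four():
    """Four clusters, two of which (L1.a, L1.b) share a lineage signature."""
    tree = {"L1": {"L1.a": 60, "L1.b": 60}, "L2": {"L2.a": 60}, "L3": {"L3.a": 60}}
    ds, _, _ = generate(HierSpec(tree=tree, n_genes=400, seed=11))
    return preprocess(ds, SYNTH_QC)


def test_merge_reduces_group_count_and_keeps_coverage(shared_signature_four):
    ds = shared_signature_four
    g0 = ClusterGrouping.singletons(ds.cluster_names)
    merged, rep = score_after_merge(ds, g0, (0, 1))
    assert merged.n_groups == g0.n_groups - 1
    assert merged.scope == g0.scope
    assert rep.celltype_number == merged.n_groups


def test_shared_signature_pair_scores_highest(shared_signature_four):
    ds = shared_signature_four
    g0 = ClusterGrouping.singletons(ds.cluster_names)
    cache = _NodeCache(ds, g0.scope, ScoringConfig(), MarkerConfig())
    scores = {}
    for i in range(4):
        for j in range(i + 1, 4):
            _, rep = score_after_merge(ds, g0, (i, j), _cache=cache)
            scores[(g0.group_label(i), g0.group_label(j))] = rep.s
    assert max(scores, key=scores.get) == ("L1.a", "L1.b")


def test_best_merge_matches_exhaustive_evaluation(shared_signature_four):
    ds = shared_signature_four
    g0 = ClusterGrouping.singletons(ds.cluster_names)
    cache = _NodeCache(ds, g0.scope, ScoringConfig(), MarkerConfig())
    step = best_merge_step(ds, g0, _cache=cache)
    assert step is not None
    # exhaustive oracle with the same tie-break
    best_key, best_s = None, -np.inf
    for i in range(g0.n_groups):
        for j in range(i + 1, g0.n_groups):
            _, rep = score_after_merge(ds, g0, (i, j), _cache=cache)
            if rep.s > best_s + 1e-9:
                best_key, best_s = (i, j), rep.s
    assert step[0].key() == g0.merge(*best_key).key()
    assert step[1].s == pytest.approx(best_s)


def test_no_improvement_on_orthogonal_clusters():
    ds, _, _ = generate(orthogonal_spec(n_clusters=4, cells_per_cluster=60, seed=2))
    pp = preprocess(ds, SYNTH_QC)
    g0 = ClusterGrouping.singletons(pp.cluster_names)
    assert best_merge_step(pp, g0) is None


def test_merge_step_requires_three_groups():
    ds, _, _ = generate(orthogonal_spec(n_clusters=2, cells_per_cluster=20, seed=0))
    pp = preprocess(ds, SYNTH_QC)
    with pytest.raises(ValidationError):
        best_merge_step(pp, ClusterGrouping.singletons(pp.cluster_names))


# -- agglomeration and hierarchy -------------------------------------------


def test_agglomerate_two_clusters_returns_singletons():
    ds, _, _ = generate(orthogonal_spec(n_clusters=2, cells_per_cluster=20, seed=0))
    pp = preprocess(ds, SYNTH_QC)
    grouping, trace = agglomerate(pp, pp.cluster_names)
    assert grouping.n_groups == 2
    assert all(len(g) == 1 for g in grouping.groups)
    assert len(trace) == 1


def test_agglomerate_outlier_plus_shared_lineage():
    # one distinct cluster plus 8 clusters sharing a lineage signature:
    # the agglomeration should end at {outlier} vs {the rest merged}
    tree = {"Lym": {f"T{i}": 40 for i in range(1, 9)}, "Plt-lin": {"Plt": 40}}
    ds, _, _ = generate(HierSpec(tree=tree, n_genes=400, seed=5))
    pp = preprocess(ds, SYNTH_QC)
    grouping, trace = agglomerate(pp, pp.cluster_names)
    assert grouping.n_groups == 2
    assert frozenset(["Plt"]) in grouping.groups
    # accepted merges strictly increase the score
    scores = [rep.s for _, rep in trace]
    assert all(b > a for a, b in zip(scores, scores[1:]))


def test_hierarchy_degenerate_equals_flat():
    ds, _, _ = generate(orthogonal_spec(n_clusters=4, cells_per_cluster=60, seed=7))
    pp = preprocess(ds, SYNTH_QC)
    root = build_hierarchy(pp)
    assert root.depth() == 1
    assert len(root.children) == 4
    flat = one_vs_all_markers(pp, ClusterGrouping.singletons(pp.cluster_names))
    assert root.split_markers.gene_lists() == flat.gene_lists()


def test_hierarchy_recovers_planted_two_level_design(planted):
    pp, truth, _ = planted
    root = build_hierarchy(pp)
    assert topology_signature(root) == expected_two_level(truth)
    assert root.depth() == 2


def test_hierarchy_leaves_are_base_clusters(planted):
    pp, _, _ = planted
    root = build_hierarchy(pp)
    leaf_labels = {next(iter(leaf.members)) for leaf in root.leaves()}
    assert leaf_labels == set(pp.cluster_names)
    for node in root.internal_nodes():
        child_union = frozenset().union(*(c.members for c in node.children))
        assert child_union == node.members


def test_hierarchy_serialization(tmp_path, planted):
    pp, _, _ = planted
    root = build_hierarchy(pp)
    path = tmp_path / "tree.json"
    root.save_json(path)
    loaded = json.loads(path.read_text())
    assert set(loaded["members"]) == set(pp.cluster_names)
    assert len(loaded["children"]) == 2
    nwk = root.to_newick()
    assert nwk.endswith(";") and all(lab in nwk for lab in pp.cluster_names)
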