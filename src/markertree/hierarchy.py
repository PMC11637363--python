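"""Score-guided agglomeration and the divisive cluster hierarchy.

The heatmap block score quantifies undesirable off-diagonal marker
expression.  For a grouping with groups 1..G and marker sets M_1..M_G, on a
chosen expression layer restricted to the in-scope cells:

    diag_i    = mean over (genes in M_i) x (cells of group i)
    offdiag_i = max over base clusters c outside group i of
                mean over (genes in M_i) x (cells of cluster c)
    s = (sum_i diag_i - k * sum_i offdiag_i) / G

The off-diagonal maximum ranges over the finest column blocks (base
clusters) rather than merged groups: averaging a marker set over a
heterogeneous merged group would dilute a strong off-diagonal signal
confined to one of its clusters, letting unrelated merges hide bleed-over
instead of removing it.

Merging two cluster groups and re-running one-vs-all marker finding changes
the score; the agglomeration greedily accepts the best-scoring merge while
it strictly improves s, and a divisive recursion over the resulting groups
yields the cluster hierarchy with split-specific markers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .dataset import ExpressionDataset
from .errors import ValidationError
from .grouping import ClusterGrouping
from .markers import DEContext, MarkerConfig, MarkerTable, one_vs_all_markers

TIE_TOL = 1e-9


@dataclass
class ScoringConfig:
    """Parameters of the heatmap block score.

    k     : weight of the off-diagonal penalty (default 5).
    layer : expression layer the implicit heatmap reads ('scaled' or
            'lognorm'); 'scaled' matches what marker heatmaps display.
    clip  : upper clip applied to the layer before averaging (default 2.5,
            the usual heatmap display ceiling); None disables.
    floor : lower clip (default 0.0): values below the per-gene baseline
            carry no expression signal, so block means measure presence of
            expression rather than depletion.  None keeps negative values,
            in which case a merge can look favorable merely because marker
            means drop below baseline elsewhere.
    """

    k: float = 5.0
    layer: str = "scaled"
    clip: Optional[float] = 2.5
    floor: Optional[float] = 0.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValidationError("k must be positive")
        if self.layer not in ("scaled", "lognorm"):
            raise ValidationError(f"unknown scoring layer {self.layer!r}")
        if self.clip is not None and self.clip <= 0:
            raise ValidationError("clip must be positive or None")
        if (
            self.clip is not None
            and self.floor is not None
            and self.floor >= self.clip
        ):
            raise ValidationError("floor must be below clip")


@dataclass
class ScoreReport:
    """Score decomposition for one grouping."""

    v_diagonal: float
    v_off_diagonal: float
    s: float
    celltype_number: int
    per_group_diag: list[float]
    per_group_max_offdiag: list[float]
    k: float

    def to_dict(self) -> dict:
        return {
            "v_diagonal": self.v_diagonal,
            "v_off_diagonal": self.v_off_diagonal,
            "s": self.s,
            "celltype_number": self.celltype_number,
            "per_group_diag": self.per_group_diag,
            "per_group_max_offdiag": self.per_group_max_offdiag,
            "k": self.k,
        }


@dataclass
class HierarchyNode:
    """A node of the divisive tree over base cluster labels."""

    members: frozenset
    children: list["HierarchyNode"] = field(default_factory=list)
    split_markers: Optional[MarkerTable] = None
    agglomeration_trace: list[tuple[ClusterGrouping, ScoreReport]] = field(
        default_factory=list
    )
    node_id: str = "n0"

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["HierarchyNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def internal_nodes(self) -> list["HierarchyNode"]:
        """Pre-order list of split nodes (nodes with children)."""
        if self.is_leaf:
            return []
        out = [self]
        for c in self.children:
            out.extend(c.internal_nodes())
        return out

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(c.depth() for c in self.children)

    def split_grouping(self) -> ClusterGrouping:
        if self.is_leaf:
            raise ValidationError("leaf node has no split")
        return ClusterGrouping(tuple(c.members for c in self.children))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {"node_id": self.node_id, "members": sorted(self.members)}
        if not self.is_leaf:
            d["children"] = [c.to_dict() for c in self.children]
            if self.split_markers is not None:
                d["split_markers"] = self.split_markers.table.to_dict("records")
                d["group_order"] = list(self.split_markers.group_order)
            d["trace"] = [
                {"groups": [sorted(g) for g in grouping.groups], **rep.to_dict()}
                for grouping, rep in self.agglomeration_trace
            ]
        return d

    def to_newick(self) -> str:
        def rec(node: "HierarchyNode") -> str:
            if node.is_leaf:
                return next(iter(node.members))
            return "(" + ",".join(rec(c) for c in node.children) + ")"

        return rec(self) + ";"

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# -- scoring ---------------------------------------------------------------


def _score_layer(ds: ExpressionDataset, cfg: ScoringConfig) -> np.ndarray:
    M = ds.layer(cfg.layer)
    lo = cfg.floor if cfg.floor is not None else (None if cfg.clip is None else -cfg.clip)
    if cfg.clip is not None or lo is not None:
        M = np.clip(M, lo, cfg.clip)
    return M


def heatmap_score(
    ds: ExpressionDataset,
    grouping: ClusterGrouping,
    markers: MarkerTable,
    cfg: ScoringConfig | None = None,
) -> ScoreReport:
    """Score a grouping's marker heatmap; higher is better.

    The diagonal term averages each group's marker block over the group's
    own cells; the off-diagonal term takes, per marker set, the maximum
    block mean over the base clusters outside the group (finest blocks, so
    a merge cannot dilute away bleed-over into one of its clusters).  A
    group with an empty marker list contributes 0 to both terms.
    """
    cfg = cfg or ScoringConfig()
    if grouping.n_groups < 2:
        raise ValidationError("score is undefined for a single group")
    M = _score_layer(ds, cfg)
    gene_pos = {g: i for i, g in enumerate(ds.gene_ids)}
    cell_masks = [ds.cells_in_clusters(grp) for grp in grouping.groups]
    if not any(m.any() for m in cell_masks):
        raise ValidationError("empty scope: no cells belong to the grouping")
    cluster_masks = {
        c: ds.cells_in_clusters([c]) for c in sorted(grouping.scope)
    }

    diag: list[float] = []
    offdiag: list[float] = []
    for i, grp_label in enumerate(grouping.group_labels):
        genes = [gene_pos[g] for g in markers.genes(grp_label)]
        if not genes:
            diag.append(0.0)
            offdiag.append(0.0)
            continue
        block = M[:, genes]
        diag.append(float(block[cell_masks[i]].mean()))
        others = [
            float(block[mask].mean())
            for c, mask in cluster_masks.items()
            if c not in grouping.groups[i]
        ]
        offdiag.append(max(others))
    v_diag = float(np.sum(diag))
    v_off = float(np.sum(offdiag))
    g = grouping.n_groups
    return ScoreReport(
        v_diagonal=v_diag,
        v_off_diagonal=v_off,
        s=(v_diag - cfg.k * v_off) / g,
        celltype_number=g,
        per_group_diag=diag,
        per_group_max_offdiag=offdiag,
        k=cfg.k,
    )


# -- agglomeration ---------------------------------------------------------


class _NodeCache:
    """Memo of (markers, score) per canonical grouping within one scope."""

    def __init__(
        self,
        ds: ExpressionDataset,
        scope: frozenset,
        cfg: ScoringConfig,
        mcfg: MarkerConfig,
    ):
        self.ds = ds
        self.cfg = cfg
        self.mcfg = mcfg
        self.ctx = DEContext.build(ds, scope)
        self._memo: dict[frozenset, tuple[MarkerTable, ScoreReport]] = {}

    def evaluate(self, grouping: ClusterGrouping) -> tuple[MarkerTable, ScoreReport]:
        key = grouping.key()
        if key not in self._memo:
            mt = one_vs_all_markers(self.ds, grouping, self.mcfg, ctx=self.ctx)
            rep = heatmap_score(self.ds, grouping, mt, self.cfg)
            self._memo[key] = (mt, rep)
        return self._memo[key]


def score_after_merge(
    ds: ExpressionDataset,
    grouping: ClusterGrouping,
    pair: tuple[int, int],
    cfg: ScoringConfig | None = None,
    mcfg: MarkerConfig | None = None,
    _cache: _NodeCache | None = None,
) -> tuple[ClusterGrouping, ScoreReport]:
    """Merge a pair of groups, re-identify markers, and score the result."""
    cfg = cfg or ScoringConfig()
    mcfg = mcfg or MarkerConfig()
    merged = grouping.merge(*pair)
    cache = _cache or _NodeCache(ds, grouping.scope, cfg, mcfg)
    _, rep = cache.evaluate(merged)
    return merged, rep


def best_merge_step(
    ds: ExpressionDataset,
    grouping: ClusterGrouping,
    cfg: ScoringConfig | None = None,
    mcfg: MarkerConfig | None = None,
    _cache: _NodeCache | None = None,
) -> Optional[tuple[ClusterGrouping, ScoreReport]]:
    """Evaluate all pairwise merges; return the best if it improves s.

    Returns None (no-improvement) when no merge beats the current grouping's
    score by more than the tie tolerance.  Candidate ties are broken by the
    smallest (i, j) index pair.
    """
    cfg = cfg or ScoringConfig()
    mcfg = mcfg or MarkerConfig()
    if grouping.n_groups < 3:
        raise ValidationError("need at least 3 groups to attempt a merge")
    cache = _cache or _NodeCache(ds, grouping.scope, cfg, mcfg)
    _, current = cache.evaluate(grouping)

    best: Optional[tuple[ClusterGrouping, ScoreReport]] = None
    best_s = -np.inf
    for i in range(grouping.n_groups):
        for j in range(i + 1, grouping.n_groups):
            merged, rep = score_after_merge(
                ds, grouping, (i, j), cfg, mcfg, _cache=cache
            )
            if rep.s > best_s + TIE_TOL:
                best, best_s = (merged, rep), rep.s
    if best is not None and best_s > current.s + TIE_TOL:
        return best
    return None


def agglomerate(
    ds: ExpressionDataset,
    scope,
    cfg: ScoringConfig | None = None,
    mcfg: MarkerConfig | None = None,
) -> tuple[ClusterGrouping, list[tuple[ClusterGrouping, ScoreReport]]]:
    """Agglomerate base clusters in `scope` from singletons upward.

    Starts from the singleton grouping and repeatedly applies
    :func:`best_merge_step` until no merge improves the score or only two
    groups remain (the score and the one-vs-all subroutine are undefined for
    a single group).  Returns the final grouping and the full score trace.
    """
    cfg = cfg or ScoringConfig()
    mcfg = mcfg or MarkerConfig()
    scope = frozenset(scope)
    if len(scope) < 2:
        raise ValidationError("agglomeration requires at least 2 base clusters")
    cache = _NodeCache(ds, scope, cfg, mcfg)
    grouping = ClusterGrouping.singletons(sorted(scope))
    _, rep = cache.evaluate(grouping)
    trace = [(grouping, rep)]
    while grouping.n_groups > 2:
        step = best_merge_step(ds, grouping, cfg, mcfg, _cache=cache)
        if step is None:
            break
        grouping, rep = step
        trace.append((grouping, rep))
    return grouping, trace


def build_hierarchy(
    ds: ExpressionDataset,
    cfg: ScoringConfig | None = None,
    mcfg: MarkerConfig | None = None,
) -> HierarchyNode:
    """Build the divisive cluster hierarchy for a labeled dataset.

    At each node, the node's member clusters are agglomerated under the
    score; the final groups become the node's children and the merged
    grouping's one-vs-all markers become the split markers.  Recursion
    descends into every child with >= 2 members until all leaves are single
    base clusters.  Each recursive call restricts the dataset to the node's
    cells; the globally scaled layer is reused.
    """
    cfg = cfg or ScoringConfig()
    mcfg = mcfg or MarkerConfig()
    if ds.cluster_labels is None:
        raise ValidationError("dataset must carry cluster labels")
    clusters = ds.cluster_names
    if len(clusters) < 2:
        raise ValidationError("hierarchy requires at least 2 base clusters")

    def rec(members: frozenset, node_id: str) -> HierarchyNode:
        node = HierarchyNode(members=members, node_id=node_id)
        if len(members) == 1:
            return node
        sub = ds.subset_cells(ds.cells_in_clusters(members))
        counts = {m: int((sub.cluster_labels == m).sum()) for m in members}
        tiny = [m for m, c in counts.items() if c < 2]
        if tiny:
            raise ValidationError(
                f"cluster(s) {sorted(tiny)} have <2 cells at node {node_id}"
            )
        grouping, trace = agglomerate(sub, members, cfg, mcfg)
        node.agglomeration_trace = trace
        node.split_markers = one_vs_all_markers(sub, grouping, mcfg)
        node.children = [
            rec(grp, f"{node_id}.{i}") for i, grp in enumerate(grouping.groups)
        ]
        return node

    return rec(frozenset(clusters), "n0")
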