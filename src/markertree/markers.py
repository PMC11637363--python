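"""One-vs-all Wilcoxon rank-sum marker gene finding.

For a grouping of cell clusters, each group is tested against all other
in-scope cells gene by gene with a two-sided Wilcoxon rank-sum test on
log-normalized expression.  Genes pass an up-regulation filter (log
fold-change of de-logged means) and a prevalence filter (fraction of
expressing cells in the group), are ranked, and truncated to the top n per
group.  The exact null distribution is enumerated for very small samples;
otherwise a tie-corrected normal approximation with continuity correction
is used.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset
from .errors import DegenerateGroupError, ValidationError
from .grouping import ClusterGrouping

_LFC_PSEUDOCOUNT = 1e-9
_EXACT_MAX_N = 12

MARKER_COLUMNS = [
    "group",
    "rank",
    "gene",
    "stat",
    "p",
    "p_adj",
    "log_fc",
    "pct_in",
    "pct_out",
]


@dataclass
class MarkerConfig:
    """Marker-finding parameters.

    n_top     : markers kept per group (13 by default, matching a ~118-gene
                budget over 9 clusters).
    lfc_min   : minimum natural-log fold-change (strict), default 0.25.
    pct_min   : minimum expressing fraction inside the group, default 0.1.
    adjust    : multiple-testing correction, 'bonferroni' or 'bh'.
    rank_by   : primary ranking key — 'p_adj' (ascending adjusted p, ties by
                descending fold-change) or 'log_fc' (descending fold-change,
                the convention marker heatmaps display).
    """

    n_top: int = 13
    lfc_min: float = 0.25
    pct_min: float = 0.1
    adjust: str = "bonferroni"
    rank_by: str = "p_adj"

    def __post_init__(self) -> None:
        if self.n_top < 1:
            raise ValidationError("n_top must be >= 1")
        if not 0.0 <= self.pct_min <= 1.0:
            raise ValidationError("pct_min must be in [0, 1]")
        if self.adjust not in ("bonferroni", "bh"):
            raise ValidationError(f"unknown adjust method {self.adjust!r}")
        if self.rank_by not in ("log_fc", "p_adj"):
            raise ValidationError(f"unknown rank_by {self.rank_by!r}")


@dataclass
class MarkerTable:
    """Ranked marker genes per group.

    ``table`` has columns (group, rank, gene, stat, p, p_adj, log_fc,
    pct_in, pct_out); within a group rows are sorted by the configured
    ranking key (adjusted p-value by default, fold-change optionally),
    with gene id as the final deterministic tie-break.
    """

    table: pd.DataFrame
    group_order: tuple[str, ...]

    def genes(self, group: str) -> list[str]:
        sub = self.table[self.table["group"] == group]
        return list(sub.sort_values("rank")["gene"])

    def gene_lists(self) -> dict[str, list[str]]:
        return {g: self.genes(g) for g in self.group_order}

    def all_genes(self) -> list[str]:
        """Distinct genes across groups, in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.group_order:
            for gene in self.genes(g):
                seen.setdefault(gene)
        return list(seen)

    @classmethod
    def from_gene_lists(
        cls, lists: dict[str, Sequence[str]], group_order: Sequence[str] | None = None
    ) -> "MarkerTable":
        """Build a minimal table from plain gene lists (stats filled with
        neutral placeholders); useful for scoring user-supplied markers."""
        order = tuple(group_order) if group_order is not None else tuple(lists)
        rows = []
        for grp in order:
            for r, gene in enumerate(lists[grp], start=1):
                rows.append((grp, r, gene, 0.0, 1.0, 1.0, 0.0, 0.0, 0.0))
        return cls(
            table=pd.DataFrame(rows, columns=MARKER_COLUMNS), group_order=order
        )

    def write_tsv(self, path, split_id: str = "root") -> None:
        out = self.table.copy()
        out.insert(0, "split_id", split_id)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "MarkerTable":
        df = pd.read_csv(path, sep="\t", dtype={"group": str, "gene": str})
        order = tuple(dict.fromkeys(df["group"]))
        return cls(table=df[MARKER_COLUMNS].copy(), group_order=order)


# -- Wilcoxon rank-sum -----------------------------------------------------


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(np.float64) ** 3 - counts))


def _normal_p(rank_sum: float, n1: int, n2: int, tie_term: float) -> tuple[float, float]:
    """Tie-corrected normal approximation with continuity correction.

    Returns (z, two-sided p)."""
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0, 1.0
    dev = abs(rank_sum - mu)
    z = np.sign(rank_sum - mu) * max(dev - 0.5, 0.0) / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return float(z), float(p)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "exact"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with midrank ties.

    Returns ``(W, p)`` where W is the rank sum of ``x`` in the pooled sample.
    ``mode='exact'`` enumerates the permutation null whenever
    ``len(x) + len(y) <= 12``; otherwise (and for ``mode='normal'``) a
    tie-corrected normal approximation with continuity correction is used.
    If all pooled values are identical the p-value is 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    n1, n = x.size, pooled.size
    w = float(ranks[:n1].sum())
    if np.all(pooled == pooled[0]):
        return w, 1.0
    if mode == "exact" and n <= _EXACT_MAX_N:
        mu = n1 * (n + 1) / 2.0
        obs_dev = abs(w - mu)
        hits = 0
        total = comb(n, n1)
        for idx in itertools.combinations(range(n), n1):
            if abs(ranks[list(idx)].sum() - mu) >= obs_dev - 1e-12:
                hits += 1
        return w, hits / total
    if mode not in ("exact", "normal"):
        raise ValidationError(f"unknown mode {mode!r}")
    _, p = _normal_p(w, n1, n - n1, _tie_term(pooled))
    return w, p


# -- vectorized context ----------------------------------------------------


@dataclass
class DEContext:
    """Per-scope precomputation shared across candidate groupings.

    Ranking of each gene across the in-scope cells (and the per-gene tie
    term) depends only on the scope, not on the grouping, so it is computed
    once per hierarchy node and reused for every candidate merge.
    """

    scope_idx: np.ndarray
    ranks: np.ndarray  # cells-in-scope x genes midranks
    tie_terms: np.ndarray  # per-gene sum(t^3 - t)
    expm: np.ndarray  # expm1(lognorm) restricted to scope
    positive: np.ndarray  # lognorm > 0 restricted to scope
    labels: np.ndarray  # base cluster label per in-scope cell
    logn: np.ndarray = None  # lognorm restricted to scope

    @classmethod
    def build(cls, ds: ExpressionDataset, scope: frozenset) -> "DEContext":
        if ds.lognorm is None:
            raise ValidationError("preprocess the dataset before marker finding")
        mask = ds.cells_in_clusters(scope)
        idx = np.flatnonzero(mask)
        X = ds.lognorm[idx]
        ranks = stats.rankdata(X, method="average", axis=0)
        tie_terms = np.array([_tie_term(X[:, j]) for j in range(X.shape[1])])
        return cls(
            scope_idx=idx,
            ranks=ranks,
            tie_terms=tie_terms,
            expm=np.expm1(X),
            positive=X > 0,
            labels=ds.cluster_labels[idx],
            logn=X,
        )

    @property
    def n_cells(self) -> int:
        return len(self.scope_idx)


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def one_vs_all_markers(
    ds: ExpressionDataset,
    grouping: ClusterGrouping,
    cfg: MarkerConfig | None = None,
    ctx: Optional[DEContext] = None,
) -> MarkerTable:
    """Find up-regulated marker genes for each group versus the rest.

    For every group the test compares log-normalized expression of the
    group's cells against all other cells in the grouping's scope.  Genes
    with ``log_fc > cfg.lfc_min`` and ``pct_in >= cfg.pct_min`` are kept,
    ranked by adjusted p-value (ties: descending log_fc, then gene id), and
    truncated to ``cfg.n_top``.  An empty post-filter list is allowed.
    """
    cfg = cfg or MarkerConfig()
    if grouping.n_groups < 2:
        raise ValidationError("marker finding requires at least 2 groups")
    if ctx is None:
        ctx = DEContext.build(ds, grouping.scope)
    n = ctx.n_cells
    gene_ids = np.asarray(ds.gene_ids)
    rows: list[pd.DataFrame] = []
    use_exact = n <= _EXACT_MAX_N

    for gi in range(grouping.n_groups):
        members = grouping.groups[gi]
        in_mask = np.fromiter(
            (lab in members for lab in ctx.labels), dtype=bool, count=n
        )
        n1 = int(in_mask.sum())
        n2 = n - n1
        if n1 < 2 or n2 < 1:
            raise DegenerateGroupError(
                f"group {grouping.group_label(gi)!r} has {n1} cells"
            )
        rank_sums = ctx.ranks[in_mask].sum(axis=0)
        if use_exact:
            stat = np.empty(len(gene_ids))
            pvals = np.empty(len(gene_ids))
            X = ctx.logn if ctx.logn is not None else np.log1p(ctx.expm)
            for j in range(len(gene_ids)):
                stat[j], pvals[j] = wilcoxon_rank_sum(
                    X[in_mask, j], X[~in_mask, j], mode="exact"
                )
        else:
            mu = n1 * (n + 1) / 2.0
            var = n1 * n2 / 12.0 * ((n + 1) - ctx.tie_terms / (n * (n - 1)))
            dev = np.abs(rank_sums - mu)
            with np.errstate(invalid="ignore", divide="ignore"):
                z = np.where(
                    var > 0,
                    np.sign(rank_sums - mu)
                    * np.maximum(dev - 0.5, 0.0)
                    / np.sqrt(np.maximum(var, 1e-300)),
                    0.0,
                )
            pvals = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z)))
            stat = z
        p_adj = _adjust(pvals, cfg.adjust)

        mean_in = ctx.expm[in_mask].mean(axis=0)
        mean_out = ctx.expm[~in_mask].mean(axis=0)
        log_fc = np.log(mean_in + _LFC_PSEUDOCOUNT) - np.log(
            mean_out + _LFC_PSEUDOCOUNT
        )
        pct_in = ctx.positive[in_mask].mean(axis=0)
        pct_out = ctx.positive[~in_mask].mean(axis=0)

        keep = (log_fc > cfg.lfc_min) & (pct_in >= cfg.pct_min)
        sub = pd.DataFrame(
            {
                "group": grouping.group_label(gi),
                "gene": gene_ids[keep],
                "stat": stat[keep],
                "p": pvals[keep],
                "p_adj": p_adj[keep],
                "log_fc": log_fc[keep],
                "pct_in": pct_in[keep],
                "pct_out": pct_out[keep],
            }
        )
        if cfg.rank_by == "log_fc":
            sort_cols = (["log_fc", "p_adj", "gene"], [False, True, True])
        else:
            sort_cols = (["p_adj", "log_fc", "gene"], [True, False, True])
        sub = sub.sort_values(
            sort_cols[0], ascending=sort_cols[1], kind="stable"
        ).head(cfg.n_top)
        sub.insert(1, "rank", np.arange(1, len(sub) + 1))
        rows.append(sub[MARKER_COLUMNS])

    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=MARKER_COLUMNS)
    )
    return MarkerTable(table=table, group_order=tuple(grouping.group_labels))
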