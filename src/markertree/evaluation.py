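"""KNN evaluation harness: within-dataset classification and cross-dataset
cell type mapping over competing gene-selection feature sets.

Accuracy is always reported per cell type (recall) and as the unweighted
macro mean over cell types, so rare types weigh as much as abundant ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import recall_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from .assembly import assemble_features
from .dataset import ExpressionDataset
from .errors import MarkerTreeError, ValidationError
from .grouping import ClusterGrouping
from .hierarchy import HierarchyNode, ScoringConfig, build_hierarchy
from .markers import MarkerConfig, one_vs_all_markers
from .preprocess import select_hvgs

SELECTORS = ("all", "hvg_overlap", "flat_markers", "hier_markers")


@dataclass
class EvalResult:
    """Per-class and macro-averaged classification accuracy."""

    per_class_accuracy: dict[str, float]
    average_accuracy: float
    n_train: int
    n_test: int
    feature_set_name: str
    seed: int
    n_neighbors: int = 15

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.feature_set_name, cls, acc)
            for cls, acc in self.per_class_accuracy.items()
        ]
        rows.append((self.feature_set_name, "Average", self.average_accuracy))
        return pd.DataFrame(rows, columns=["selector", "class", "accuracy"])

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_set_name": self.feature_set_name,
                "per_class_accuracy": self.per_class_accuracy,
                "average_accuracy": self.average_accuracy,
                "n_train": self.n_train,
                "n_test": self.n_test,
                "seed": self.seed,
                "n_neighbors": self.n_neighbors,
            },
            indent=2,
        )


def _per_class(y_true, y_pred) -> dict[str, float]:
    classes = sorted(set(y_true))
    rec = recall_score(y_true, y_pred, labels=classes, average=None, zero_division=0)
    return {c: float(r) for c, r in zip(classes, rec)}


def knn_within(
    features: np.ndarray,
    labels,
    train_frac: float = 0.7,
    n_neighbors: int = 15,
    seed: int = 0,
    feature_set_name: str = "features",
) -> EvalResult:
    """Stratified 70/30 split, Euclidean KNN, per-class recall on the test set."""
    if not 0.0 < train_frac < 1.0:
        raise ValidationError("train_frac must be in (0, 1)")
    labels = np.asarray(labels, dtype=object)
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValidationError("every class needs >= 2 cells for a stratified split")
    try:
        X_tr, X_te, y_tr, y_te = train_test_split(
            np.asarray(features),
            labels,
            train_size=train_frac,
            stratify=labels,
            random_state=seed,
        )
    except ValueError as exc:
        raise ValidationError(f"stratified split failed: {exc}") from exc
    missing = (set(labels) - set(y_tr)) | (set(labels) - set(y_te))
    if missing:
        raise ValidationError(f"classes absent from train or test split: {missing}")
    clf = KNeighborsClassifier(n_neighbors=min(n_neighbors, len(y_tr)))
    clf.fit(X_tr, y_tr)
    pred = clf.predict(X_te)
    per_class = _per_class(y_te, pred)
    return EvalResult(
        per_class_accuracy=per_class,
        average_accuracy=float(np.mean(list(per_class.values()))),
        n_train=len(y_tr),
        n_test=len(y_te),
        feature_set_name=feature_set_name,
        seed=seed,
        n_neighbors=n_neighbors,
    )


# -- cross-dataset mapping -------------------------------------------------


def _reference_features(
    ref: ExpressionDataset,
    query: ExpressionDataset,
    selector: str,
    mcfg: MarkerConfig,
    scfg: ScoringConfig,
    layer: str,
):
    """Choose feature genes on the reference only and build both matrices."""
    shared = [g for g in ref.gene_ids if g in set(query.gene_ids)]
    if not shared:
        raise MarkerTreeError("reference and query share no genes")
    qpos = {g: i for i, g in enumerate(query.gene_ids)}
    rpos = {g: i for i, g in enumerate(ref.gene_ids)}

    if selector == "all":
        genes = shared
    elif selector == "hvg_overlap":
        # intersection of independently selected HVGs, the cross-dataset
        # convention for the HVG baseline
        hv_ref = {g for g, s in zip(ref.gene_ids, select_hvgs(ref).selected) if s}
        hv_query = {g for g, s in zip(query.gene_ids, select_hvgs(query).selected) if s}
        genes = [g for g in shared if g in hv_ref and g in hv_query]
    elif selector == "flat_markers":
        grouping = ClusterGrouping.singletons(ref.cluster_names)
        mt = one_vs_all_markers(ref, grouping, mcfg)
        genes = [g for g in mt.all_genes() if g in qpos]
    elif selector == "hier_markers":
        root = build_hierarchy(ref, scfg, mcfg)
        am = assemble_features(ref, root, layer=layer)
        keep = am.feature_meta["gene"].isin(qpos).to_numpy()
        ref_X = am.values[:, keep]
        qcols = [qpos[g] for g in am.feature_meta["gene"][keep]]
        # query cluster membership is unknown at prediction time, so query
        # cells take full (unmasked) expression over every split feature
        query_X = query.layer(layer)[:, qcols]
        return ref_X, query_X, list(am.feature_meta["gene"][keep])
    else:
        raise ValidationError(f"unknown selector {selector!r}")

    if not genes:
        raise MarkerTreeError(f"selector {selector!r} produced no shared genes")
    ref_X = ref.layer(layer)[:, [rpos[g] for g in genes]]
    query_X = query.layer(layer)[:, [qpos[g] for g in genes]]
    return ref_X, query_X, genes


def cross_dataset_map(
    ref: ExpressionDataset,
    query: ExpressionDataset,
    selector: str = "hier_markers",
    n_neighbors: int = 15,
    seed: int = 0,
    mcfg: MarkerConfig | None = None,
    scfg: ScoringConfig | None = None,
    layer: str = "scaled",
) -> EvalResult:
    """Train on a labeled reference, predict cell types of a query dataset.

    Feature genes are chosen on the reference only.  Both datasets must be
    preprocessed, share a gene namespace and the same label vocabulary.
    """
    mcfg = mcfg or MarkerConfig()
    scfg = scfg or ScoringConfig()
    ref_labels = set(ref.cluster_names)
    q_labels = set(query.cluster_names)
    if ref_labels != q_labels:
        raise MarkerTreeError(
            "label vocabulary mismatch; symmetric difference: "
            f"{sorted(ref_labels ^ q_labels)}"
        )
    ref_X, query_X, _ = _reference_features(ref, query, selector, mcfg, scfg, layer)
    clf = KNeighborsClassifier(n_neighbors=min(n_neighbors, ref.n_cells))
    clf.fit(ref_X, np.asarray(ref.cluster_labels, dtype=object))
    pred = clf.predict(query_X)
    per_class = _per_class(np.asarray(query.cluster_labels, dtype=object), pred)
    return EvalResult(
        per_class_accuracy=per_class,
        average_accuracy=float(np.mean(list(per_class.values()))),
        n_train=ref.n_cells,
        n_test=query.n_cells,
        feature_set_name=selector,
        seed=seed,
        n_neighbors=n_neighbors,
    )


def plot_accuracy_bars(results: list[EvalResult], out) -> None:
    """Grouped bar chart of per-class and average accuracy per feature set."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.concat([r.to_frame() for r in results], ignore_index=True)
    classes = list(dict.fromkeys(df["class"]))
    selectors = list(dict.fromkeys(df["selector"]))
    width = 0.8 / max(1, len(selectors))
    fig, ax = plt.subplots(figsize=(max(6, len(classes) * 0.9), 4))
    x = np.arange(len(classes))
    for i, sel in enumerate(selectors):
        sub = df[df["selector"] == sel].set_index("class")["accuracy"]
        ax.bar(x + i * width, [sub.get(c, np.nan) for c in classes], width, label=sel)
    ax.set_xticks(x + width * (len(selectors) - 1) / 2)
    ax.set_xticklabels(classes, rotation=45, ha="right")
    ax.set_ylabel("classification accuracy")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
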