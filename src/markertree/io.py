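"""Readers and writers for standard expression-data formats.

Supported inputs: a 10x Genomics MTX triplet directory (``matrix.mtx[.gz]``,
``barcodes.tsv[.gz]``, ``features.tsv[.gz]`` or ``genes.tsv[.gz]``), a dense
delimited matrix, or an ``.h5ad`` file.  Cluster labels come from a two-column
TSV with header ``cell_id<TAB>cluster``.  Processed datasets round-trip
through ``.h5ad`` (AnnData with counts in ``X`` and derived layers).
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Optional, Union

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .dataset import ExpressionDataset
from .errors import ConsistencyError, FormatError, LabelingError, ValidationError

PathLike = Union[str, Path]


def _dedupe_ids(ids: list[str]) -> list[str]:
    """Disambiguate duplicate identifiers with a deterministic -N suffix."""
    return list(ad.utils.make_index_unique(pd.Index(ids), join="-"))


def _find_triplet_file(directory: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            cand = directory / (stem + suffix)
            if cand.exists():
                return cand
    raise FormatError(f"none of {stems} found in {directory}")


def _read_tsv_column(path: Path, column: int = 0) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    return [row[min(column, len(row) - 1)] for row in rows]


def read_counts(
    path: PathLike,
    format: str = "mtx_dir",
    orientation: str = "cells_by_genes",
) -> ExpressionDataset:
    """Read a raw count matrix into an :class:`ExpressionDataset`.

    Parameters
    ----------
    path
        Directory (``mtx_dir``) or file (``dense_tsv``, ``h5ad``).
    format
        One of ``mtx_dir``, ``dense_tsv``, ``h5ad``.
    orientation
        For ``dense_tsv`` only: whether rows are cells (``cells_by_genes``)
        or genes (``genes_by_cells``).

    The returned dataset has only the counts layer; cluster labels are
    attached separately with :func:`attach_labels`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"path does not exist: {path}")

    if format == "mtx_dir":
        mtx_path = _find_triplet_file(path, ("matrix.mtx",))
        barcodes = _read_tsv_column(
            _find_triplet_file(path, ("barcodes.tsv",)), column=0
        )
        features_path = _find_triplet_file(path, ("features.tsv", "genes.tsv"))
        # 10x features files carry (id, symbol, type); use the symbol column
        # when present so duplicates exercise the suffix scheme.
        feat_rows = _read_tsv_column(features_path, column=1)
        try:
            mat = scipy.io.mmread(str(mtx_path))
        except Exception as exc:  # malformed header / body
            raise FormatError(f"cannot parse MTX file {mtx_path}: {exc}") from exc
        mat = scipy.sparse.coo_matrix(mat)
        # 10x convention: rows are features, columns are barcodes.
        if mat.shape != (len(feat_rows), len(barcodes)):
            raise ConsistencyError(
                f"matrix shape {mat.shape} does not match "
                f"{len(feat_rows)} features x {len(barcodes)} barcodes"
            )
        counts = np.asarray(mat.todense()).T
    elif format == "dense_tsv":
        # read the header ourselves: pandas silently mangles duplicate
        # column names, which must instead go through the suffix scheme
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        df = pd.read_csv(path, sep="\t", index_col=0, header=None, skiprows=1)
        df.columns = header[1:]
        if orientation == "genes_by_cells":
            df = df.T
        elif orientation != "cells_by_genes":
            raise FormatError(f"unknown orientation {orientation!r}")
        counts = df.to_numpy()
        barcodes = [str(i) for i in df.index]
        feat_rows = [str(c) for c in df.columns]
    elif format == "h5ad":
        adata = ad.read_h5ad(path)
        X = adata.layers.get("counts", adata.X)
        counts = np.asarray(X.todense()) if scipy.sparse.issparse(X) else np.asarray(X)
        barcodes = list(adata.obs_names)
        feat_rows = list(adata.var_names)
    else:
        raise FormatError(f"unknown format {format!r}")

    if np.any(counts < 0):
        raise ValidationError("count matrix contains negative entries")
    if not np.allclose(counts, np.round(counts)):
        raise ValidationError("count matrix contains non-integer entries")

    return ExpressionDataset(
        counts=counts.astype(np.int64),
        cell_ids=_dedupe_ids([str(b) for b in barcodes]),
        gene_ids=_dedupe_ids([str(g) for g in feat_rows]),
    )


def read_labels(path: PathLike) -> pd.DataFrame:
    """Read a (cell_id, cluster) TSV with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["cell_id", "cluster"]:
        raise FormatError(
            "labels TSV must have header 'cell_id<TAB>cluster', "
            f"got {list(df.columns)}"
        )
    return df


def attach_labels(
    ds: ExpressionDataset, labels: Union[pd.DataFrame, PathLike]
) -> ExpressionDataset:
    """Attach per-cell cluster labels; every cell must appear exactly once.

    Raises :class:`LabelingError` on missing, duplicate or unknown cell ids,
    and :class:`ValidationError` if any cluster has fewer than 2 cells.
    """
    if not isinstance(labels, pd.DataFrame):
        labels = read_labels(labels)
    dup = labels["cell_id"][labels["cell_id"].duplicated()]
    if len(dup):
        raise LabelingError(f"duplicate cell_ids in labels: {sorted(set(dup))[:5]}")
    mapping = dict(zip(labels["cell_id"], labels["cluster"]))
    missing = [c for c in ds.cell_ids if c not in mapping]
    if missing:
        raise LabelingError(f"labels missing for cells: {missing[:5]}")
    unknown = sorted(set(mapping) - set(ds.cell_ids))
    if unknown:
        raise LabelingError(f"labels reference unknown cells: {unknown[:5]}")
    out = ExpressionDataset(
        counts=ds.counts,
        cell_ids=ds.cell_ids,
        gene_ids=ds.gene_ids,
        lognorm=ds.lognorm,
        scaled=ds.scaled,
        cluster_labels=np.array([mapping[c] for c in ds.cell_ids], dtype=object),
    )
    out.validate_labels()
    return out


# -- container round-trip --------------------------------------------------


def to_anndata(ds: ExpressionDataset) -> ad.AnnData:
    adata = ad.AnnData(
        X=ds.counts.astype(np.float64),
        obs=pd.DataFrame(index=pd.Index(ds.cell_ids, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(ds.gene_ids, name="gene_id")),
    )
    adata.layers["counts"] = ds.counts
    if ds.lognorm is not None:
        adata.layers["lognorm"] = ds.lognorm
    if ds.scaled is not None:
        adata.layers["scaled"] = ds.scaled
    if ds.cluster_labels is not None:
        adata.obs["cluster"] = pd.Categorical(ds.cluster_labels)
    return adata


def from_anndata(adata: ad.AnnData) -> ExpressionDataset:
    def dense(x):
        return np.asarray(x.todense()) if scipy.sparse.issparse(x) else np.asarray(x)

    labels = None
    if "cluster" in adata.obs:
        labels = np.asarray(adata.obs["cluster"].astype(str), dtype=object)
    return ExpressionDataset(
        counts=dense(adata.layers.get("counts", adata.X)).astype(np.int64),
        cell_ids=list(adata.obs_names),
        gene_ids=list(adata.var_names),
        lognorm=dense(adata.layers["lognorm"]) if "lognorm" in adata.layers else None,
        scaled=dense(adata.layers["scaled"]) if "scaled" in adata.layers else None,
        cluster_labels=labels,
    )


def save_dataset(ds: ExpressionDataset, path: PathLike) -> None:
    """Serialize the dataset container to an HDF5-backed ``.h5ad`` file."""
    to_anndata(ds).write_h5ad(Path(path))


def load_dataset(path: PathLike) -> ExpressionDataset:
    return from_anndata(ad.read_h5ad(Path(path)))


# -- writers ---------------------------------------------------------------


def write_mtx_dir(ds: ExpressionDataset, directory: PathLike) -> None:
    """Write the counts layer as an uncompressed 10x-style MTX triplet."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # 10x orientation: features x barcodes
    scipy.io.mmwrite(
        str(directory / "matrix.mtx"), scipy.sparse.csr_matrix(ds.counts.T)
    )
    (directory / "barcodes.tsv").write_text("\n".join(ds.cell_ids) + "\n")
    (directory / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in ds.gene_ids)
    )


def write_labels_tsv(ds: ExpressionDataset, path: PathLike) -> None:
    if ds.cluster_labels is None:
        raise ValidationError("dataset has no cluster labels to write")
    pd.DataFrame(
        {"cell_id": ds.cell_ids, "cluster": ds.cluster_labels}
    ).to_csv(path, sep="\t", index=False)


def write_qc_report(
    before: ExpressionDataset,
    after: ExpressionDataset,
    path: PathLike,
    mito_prefix: str = "MT-",
) -> pd.DataFrame:
    """Per-cell QC metrics with a kept/removed flag, written as TSV."""
    kept = set(after.cell_ids)
    n_genes = (before.counts > 0).sum(axis=1)
    total = before.counts.sum(axis=1)
    mito_cols = [i for i, g in enumerate(before.gene_ids) if g.startswith(mito_prefix)]
    mito = before.counts[:, mito_cols].sum(axis=1) if mito_cols else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    report = pd.DataFrame(
        {
            "cell_id": before.cell_ids,
            "n_genes_detected": n_genes,
            "total_counts": total,
            "mito_fraction": frac,
            "kept": [c in kept for c in before.cell_ids],
        }
    )
    report.to_csv(path, sep="\t", index=False)
    return report


def write_truth_json(truth: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
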