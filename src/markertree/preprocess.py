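"""QC filtering, normalization, scaling and highly-variable-gene selection.

The preprocessing chain mirrors the standard single-cell tutorial pipeline:
remove low-complexity / high-mitochondrial cells, normalize every cell to a
common library size, log1p, then z-score each gene.  HVG selection follows
the classic dispersion recipe: per-gene mean and dispersion (variance/mean)
on de-logged data, 20 bins by mean expression, z-normalization of log
dispersions within each bin, and a threshold triplet on mean bounds and
dispersion z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, QCConfig
from .errors import EmptyDatasetError, ValidationError


@dataclass
class HVGResult:
    """Per-gene HVG statistics.

    mean         : log1p of the per-gene mean of de-logged expression
                   (the scale the mean bounds apply to).
    dispersion   : variance/mean of de-logged expression (0 where mean is 0).
    dispersion_z : within-bin z-score of log dispersion (NaN where undefined).
    selected     : boolean mask of highly variable genes.
    """

    selected: np.ndarray
    mean: np.ndarray
    dispersion: np.ndarray
    dispersion_z: np.ndarray
    n_bins: int

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


def preprocess(ds: ExpressionDataset, cfg: QCConfig | None = None) -> ExpressionDataset:
    """Apply QC filtering, library-size normalization, log1p and scaling.

    Cells detecting fewer than ``cfg.min_genes_per_cell`` genes or exceeding
    ``cfg.max_mito_fraction`` mitochondrial counts are removed; the gene set
    is unchanged.  ``lognorm[i, j] = log1p(target_sum * counts[i, j] /
    library_size_i)``; ``scaled`` is the per-gene z-score of lognorm with
    zero-variance genes mapped to 0, clipped to ``±cfg.clip_value``.
    """
    cfg = cfg or QCConfig()
    n_detected = (ds.counts > 0).sum(axis=1)
    total = ds.counts.sum(axis=1)
    mito_cols = [i for i, g in enumerate(ds.gene_ids) if g.startswith(cfg.mito_prefix)]
    mito = (
        ds.counts[:, mito_cols].sum(axis=1)
        if mito_cols
        else np.zeros_like(total)
    )
    frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    keep = (n_detected >= cfg.min_genes_per_cell) & (frac <= cfg.max_mito_fraction)
    if not keep.any():
        raise EmptyDatasetError("QC removed every cell")
    out = ds.subset_cells(keep)

    lib = out.counts.sum(axis=1).astype(np.float64)
    lib[lib == 0] = 1.0  # a zero-count cell survives QC only if min_genes==0
    lognorm = np.log1p(cfg.target_sum * out.counts / lib[:, None])

    mu = lognorm.mean(axis=0)
    sd = lognorm.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, (lognorm - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    if cfg.clip_value is not None:
        scaled = np.clip(scaled, -cfg.clip_value, cfg.clip_value)

    out.lognorm = lognorm
    out.scaled = scaled
    if out.cluster_labels is not None:
        out.validate_labels()
    return out


def select_hvgs(
    ds: ExpressionDataset,
    n_bins: int = 20,
    min_mean: float = 0.0125,
    max_mean: float = 3.0,
    min_disp: float = 0.5,
) -> HVGResult:
    """Select highly variable genes by binned-dispersion z-scores.

    Works on de-logged normalized expression (``expm1(lognorm)``): per-gene
    mean and dispersion = variance/mean, genes cut into ``n_bins`` equal-width
    bins of log1p(mean), log dispersions z-scored within each bin, and genes
    selected when ``min_mean < log1p(mean) < max_mean`` and the dispersion
    z-score exceeds ``min_disp``.  Defaults are the de facto defaults of the
    standard recipe.
    """
    if ds.lognorm is None:
        raise ValidationError("preprocess the dataset before HVG selection")
    X = np.expm1(ds.lognorm)
    n_genes = X.shape[1]
    if n_genes < n_bins:
        warnings.warn(
            f"only {n_genes} genes for {n_bins} bins; reducing bin count",
            stacklevel=2,
        )
        n_bins = max(1, n_genes)

    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion_raw = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    # z-scoring operates on log dispersion; zero dispersion drops out as NaN
    with np.errstate(divide="ignore"):
        log_disp = np.where(dispersion_raw > 0, np.log(dispersion_raw), np.nan)
    log_mean = np.log1p(mean)

    df = pd.DataFrame({"mean": log_mean, "disp": log_disp})
    df["bin"] = pd.cut(df["mean"], bins=n_bins)
    grouped = df.groupby("bin", observed=True)["disp"]
    bin_mu = grouped.transform("mean")
    bin_sd = grouped.transform(lambda s: s.std(ddof=1))
    # single-gene bins have undefined spread: follow the standard recipe and
    # treat the lone gene's deviation as its own scale (z becomes 1)
    lone = bin_sd.isna() | (bin_sd == 0)
    bin_sd = bin_sd.where(~lone, bin_mu.abs())
    bin_mu = bin_mu.where(~lone, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp_z = (df["disp"] - bin_mu) / bin_sd
    disp_z = disp_z.to_numpy()

    selected = (
        (log_mean > min_mean)
        & (log_mean < max_mean)
        & (np.nan_to_num(disp_z, nan=-np.inf) > min_disp)
    )
    return HVGResult(
        selected=selected,
        mean=log_mean,
        dispersion=dispersion_raw,
        dispersion_z=disp_z,
        n_bins=n_bins,
    )
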