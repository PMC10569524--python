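"""Quality-control filters, CP10K log normalization, and the detection-rate covariate.

The filter order is fixed: genes detected in too few cells are
dropped first, per-cell metrics are then (re)computed on the filtered gene
space, and cells are filtered last.  Cell bounds are inclusive; the mito and
gene-count exclusions are strict ("fewer than", "greater than").
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import scipy.sparse as sp

REGION_MITO_DEFAULTS = {"cortex": 8.0, "hippocampus": 15.0}


def compute_cell_metrics(adata: ad.AnnData) -> ad.AnnData:
    """Populate per-cell n_genes_detected and mito_pct from the counts."""
    X = sp.csr_matrix(adata.X)
    adata.obs["n_genes_detected"] = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel().astype(float)
    if "is_mito" in adata.var.columns:
        mito_mask = adata.var["is_mito"].to_numpy().astype(bool)
        mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel().astype(float)
    else:
        mito = np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * mito / total, 0.0)
    adata.obs["mito_pct"] = pct
    return adata


def filter_genes(adata: ad.AnnData, min_cells: int = 4) -> ad.AnnData:
    """Keep genes detected (count > 0) in at least ``min_cells`` cells."""
    X = sp.csc_matrix(adata.X)
    detected_in = np.asarray((X > 0).sum(axis=0)).ravel()
    keep = detected_in >= min_cells
    return adata[:, keep].copy()


def filter_cells(adata: ad.AnnData, min_genes: int = 1000, max_genes: int = 5000,
                 max_mito_pct: float | None = None) -> ad.AnnData:
    """Keep cells with min_genes <= n_genes_detected <= max_genes and
    mito_pct <= max_mito_pct (region default: 8 for cortex, 15 for hippocampus).
    """
    if "n_genes_detected" not in adata.obs or "mito_pct" not in adata.obs:
        compute_cell_metrics(adata)
    if max_mito_pct is None:
        regions = set(map(str, adata.obs.get("region", []).unique())) \
            if "region" in adata.obs else set()
        if len(regions) != 1 or next(iter(regions)) not in REGION_MITO_DEFAULTS:
            raise ValueError(
                "no mito threshold given and region is missing, mixed, or has "
                f"no default (regions seen: {sorted(regions)})")
        max_mito_pct = REGION_MITO_DEFAULTS[next(iter(regions))]
    ng = adata.obs["n_genes_detected"].to_numpy()
    mito = adata.obs["mito_pct"].to_numpy()
    keep = (ng >= min_genes) & (ng <= max_genes) & (mito <= max_mito_pct)
    return adata[keep].copy()


def normalize_cp10k_log(adata: ad.AnnData) -> ad.AnnData:
    """Add a "lognorm" layer: ln(1 + 10000 * count / cell_total).

    Zero counts stay exactly zero; the raw counts layer is retained in X.
    """
    X = sp.csr_matrix(adata.X, dtype=float)
    total = np.asarray(X.sum(axis=1)).ravel()
    if (total <= 0).any():
        raise ValueError("cells with zero total counts cannot be normalized "
                         "(filter cells first)")
    norm = X.multiply(1.0 / total[:, None]).tocsr()
    norm.data = np.log1p(1e4 * norm.data)
    adata.layers["lognorm"] = norm
    return adata


def compute_cdr(adata: ad.AnnData) -> ad.AnnData:
    """Centered detection rate: fraction of genes detected per cell, mean-centered.

    This is the "ngeneson" nuisance covariate of the hurdle model.
    """
    X = sp.csr_matrix(adata.X)
    frac = np.asarray((X > 0).sum(axis=1)).ravel() / adata.n_vars
    adata.obs["cdr"] = frac - frac.mean()
    return adata


def qc_pipeline(adata: ad.AnnData, min_cells: int = 4, min_genes: int = 1000,
                max_genes: int = 5000, max_mito_pct: float | None = None) -> ad.AnnData:
    """Full QC in the fixed order: genes -> metrics -> cells -> normalize -> cdr."""
    adata = filter_genes(adata, min_cells=min_cells)
    compute_cell_metrics(adata)
    adata = filter_cells(adata, min_genes=min_genes, max_genes=max_genes,
                         max_mito_pct=max_mito_pct)
    normalize_cp10k_log(adata)
    compute_cdr(adata)
    return adata
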