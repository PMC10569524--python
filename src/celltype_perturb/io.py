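"""Readers and writers for the plain-text interchange formats.

10x-style MTX triplet (MatrixMarket integer coordinate, genes x cells) plus
features/barcodes and metadata TSVs; GMT gene sets; BED (0-based half-open)
binding-site intervals; genes x compounds reference-signature TSVs; long CSV
phenotype tables.
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def write_10x(adata: ad.AnnData, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    # MatrixMarket convention here: genes as rows, cells as columns
    mat = sp.coo_matrix(adata.X.T)
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), mat, field="integer")
    pd.Series(adata.var_names).to_csv(
        os.path.join(outdir, "features.tsv"), sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False, header=False)
    adata.var.to_csv(os.path.join(outdir, "gene_metadata.tsv"), sep="\t")
    adata.obs.to_csv(os.path.join(outdir, "cell_metadata.tsv"), sep="\t")


def read_10x(indir) -> ad.AnnData:
    mat = scipy.io.mmread(os.path.join(indir, "matrix.mtx"))
    X = sp.csr_matrix(mat.T.astype(np.int32))
    genes = pd.read_csv(os.path.join(indir, "features.tsv"),
                        sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(os.path.join(indir, "barcodes.tsv"),
                           sep="\t", header=None)[0].astype(str)
    var = pd.read_csv(os.path.join(indir, "gene_metadata.tsv"),
                      sep="\t", index_col=0)
    obs = pd.read_csv(os.path.join(indir, "cell_metadata.tsv"),
                      sep="\t", index_col=0)
    var = var.loc[genes]
    obs = obs.loc[barcodes]
    return ad.AnnData(X=X, obs=obs, var=var)


def write_gmt(gene_sets: dict[str, set], path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_gmt(path) -> dict[str, set]:
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def gene_sets_from_var(var: pd.DataFrame) -> dict[str, set]:
    """Collect set_<name> boolean columns of a gene annotation into GMT-style sets."""
    out = {}
    for col in var.columns:
        if col.startswith("set_"):
            out[col[4:]] = set(var.index[var[col].astype(bool)])
    return out


def write_bed(sites: pd.DataFrame, path) -> None:
    sites[["gene", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["gene", "start", "end"],
                     dtype={"gene": str, "start": int, "end": int})
    return df


def write_signatures(z: pd.DataFrame, meta: pd.DataFrame, prefix) -> None:
    z.to_csv(f"{prefix}_signatures.tsv", sep="\t")
    meta.to_csv(f"{prefix}_compound_metadata.tsv", sep="\t")


def read_signatures(prefix) -> tuple[pd.DataFrame, pd.DataFrame]:
    z = pd.read_csv(f"{prefix}_signatures.tsv", sep="\t", index_col=0)
    # keep_default_na: a compound role literally named "null" is data, not NA
    meta = pd.read_csv(f"{prefix}_compound_metadata.tsv", sep="\t", index_col=0,
                       keep_default_na=False)
    return z, meta
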