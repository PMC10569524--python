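"""Per-gene CLIP binding-site counting, length normalization, and percentile ranking.

Binding sites arrive as 0-based half-open intervals per gene; the unit of
analysis is the site count (not nucleotide coverage), normalized to sites per
kilobase of the supplied length column.  Percentiles use the strictly-smaller
rule over the *other* genes, so a gene above the 0.99 percentile has more
density than 99% of the other genes assessed; ties rank low.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def count_sites_per_gene(sites: pd.DataFrame, genes: pd.Index | list) -> pd.Series:
    """Number of intervals assigned to each gene; genes with none get 0."""
    genes = pd.Index(genes)
    if len(sites):
        unknown = set(sites["gene"]) - set(genes)
        if unknown:
            raise ValueError(f"intervals reference unknown genes: {sorted(unknown)[:5]}")
        counts = sites.groupby("gene").size()
    else:
        counts = pd.Series(dtype=int)
    return counts.reindex(genes, fill_value=0).astype(int).rename("n_sites")


def density_per_kb(counts: pd.Series, lengths_bp: pd.Series) -> pd.Series:
    """sites_per_kb = 1000 * n_sites / length_bp."""
    lengths = lengths_bp.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("all gene lengths must be present and positive")
    return (1000.0 * counts / lengths).rename("sites_per_kb")


def percentile_rank(values: pd.Series, gene: str) -> float:
    """Fraction of OTHER genes with a strictly smaller value (ties rank low)."""
    if gene not in values.index:
        raise KeyError(gene)
    if len(values) < 2:
        raise ValueError("need at least 2 genes to rank")
    v = float(values.loc[gene])
    others = values.drop(gene).to_numpy(dtype=float)
    return float((others < v).sum() / len(others))


def ecdf(values: pd.Series) -> pd.DataFrame:
    """Empirical CDF over genes: sorted value vs cumulative fraction (ends at 1)."""
    x = np.sort(values.to_numpy(dtype=float))
    frac = np.arange(1, len(x) + 1) / len(x)
    return pd.DataFrame({"value": x, "cum_fraction": frac})


def density_profile(sites: pd.DataFrame, gene_annotation: pd.DataFrame,
                    length_column: str = "length_bp") -> pd.DataFrame:
    """Full per-gene profile: site counts, per-kb density, and percentile.

    ``length_column`` selects the normalizing length annotation (gene vs
    transcript length, whichever the annotation supplies).
    """
    counts = count_sites_per_gene(sites, gene_annotation.index)
    dens = density_per_kb(counts, gene_annotation[length_column])
    prof = pd.DataFrame({"n_sites": counts, "sites_per_kb": dens})
    prof["percentile_count"] = [percentile_rank(counts.astype(float), g)
                                for g in prof.index]
    prof["percentile_density"] = [percentile_rank(dens, g) for g in prof.index]
    return prof
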