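"""Downsampled DEG-burden ranking and direction-stratified disease-gene enrichment.

To compare transcriptomic perturbation across cell populations on equal
footing, cells are downsampled to a fixed number per genotype within each
population (sexes pooled), differential expression is re-run with the sex
covariate removed, and populations are ranked by their count of significant
genes.  Disease-gene enrichment contrasts significant genes of one direction
against non-significant genes with a Fisher exact test, over the universe of
tested genes that have a human homolog.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .de import de_table


def downsample_cells(adata: ad.AnnData, n: int = 300,
                     seed: int = 0) -> tuple[ad.AnnData, pd.DataFrame]:
    """Sample ``n`` cells per genotype within each population, without replacement.

    Populations lacking ``n`` cells in either genotype are excluded and
    reported with a reason.  Returns (downsampled AnnData, exclusions table).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    keep_idx: list[np.ndarray] = []
    exclusions = []
    cell_types = adata.obs["cell_type"].astype(str)
    genotype = adata.obs["genotype"].astype(str)
    for ct in sorted(cell_types.unique()):
        per_gt = {}
        short = None
        for gt in ("WT", "HET"):
            idx = np.flatnonzero((cell_types == ct) & (genotype == gt))
            if len(idx) < n:
                short = (gt, len(idx))
                break
            per_gt[gt] = idx
        if short is not None:
            exclusions.append(
                (ct, f"only {short[1]} {short[0]} cells, need {n}"))
            continue
        for gt in ("WT", "HET"):
            chosen = rng.choice(per_gt[gt], size=n, replace=False)
            keep_idx.append(np.sort(chosen))
    excl = pd.DataFrame(exclusions, columns=["population", "reason"])
    if not keep_idx:
        return adata[[]].copy(), excl
    rows = np.sort(np.concatenate(keep_idx))
    return adata[rows].copy(), excl


@dataclass
class BurdenResult:
    population: str
    n_deg: int
    n_cells_used: int
    excluded: bool = False
    reason: str = ""


def deg_burden(adata_down: ad.AnnData, exclusions: pd.DataFrame | None = None,
               lfc_min: float = 0.14, fdr_max: float = 0.05,
               min_cells_detected: int = 3) -> pd.DataFrame:
    """Per-population significant-gene counts on downsampled data.

    Runs the hurdle DE with the cdr covariate only (sex removed, sexes pooled)
    and returns a table sorted by descending burden; excluded populations are
    appended with their reason and a zero count.
    """
    pops = sorted(adata_down.obs["cell_type"].astype(str).unique())
    if not pops:
        raise ValueError("all populations were excluded by downsampling")
    rows = []
    for pop in pops:
        tbl = de_table(adata_down, pop, sex_covariate=False, lfc_min=lfc_min,
                       fdr_max=fdr_max, min_cells_detected=min_cells_detected)
        n_cells = int((adata_down.obs["cell_type"].astype(str) == pop).sum())
        rows.append({"population": pop, "n_deg": int(tbl["significant"].sum()),
                     "n_cells_used": n_cells, "excluded": False, "reason": ""})
    out = pd.DataFrame(rows).sort_values(
        ["n_deg", "population"], ascending=[False, True]).reset_index(drop=True)
    if exclusions is not None and len(exclusions):
        extra = pd.DataFrame({
            "population": exclusions["population"],
            "n_deg": 0, "n_cells_used": 0,
            "excluded": True, "reason": exclusions["reason"],
        })
        out = pd.concat([out, extra], ignore_index=True)
    return out


def disease_enrichment(detable: pd.DataFrame, gene_set: set, direction: str,
                       has_homolog: pd.Series | None = None) -> dict:
    """Fisher enrichment of a disease gene set among one direction's DEGs.

    The universe is the tested genes (restricted to those with a human
    homolog when ``has_homolog`` is provided); significant genes of the
    opposite direction are excluded from both rows.  The 2x2 table is
    {significant-in-direction vs non-significant} x {in set vs not}; the
    reported odds ratio is the sample odds ratio ad/bc with a two-sided
    Fisher exact p-value.
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    t = detable[detable["tested"]].copy()
    if has_homolog is not None:
        t = t[t["gene"].map(has_homolog).fillna(False).astype(bool)]
    if len(t) == 0:
        raise ValueError("empty gene universe")
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    sig_dir = t["significant"] & (t["direction"] == direction)
    sig_opp = t["significant"] & (t["direction"] != direction)
    t = t[~sig_opp]
    in_set = t["gene"].isin(gene_set)
    sig = sig_dir.loc[t.index]
    a = int((sig & in_set).sum())
    b = int((sig & ~in_set).sum())
    c = int((~sig & in_set).sum())
    d = int((~sig & ~in_set).sum())
    table = np.array([[a, b], [c, d]])
    if b * c == 0:
        odds = np.inf if a * d > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    if a == 0:
        odds = 0.0
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "direction": direction,
        "table": table,
        "odds_ratio": float(odds),
        "p": float(p),
        "n_sig_in_set": a,
        "n_universe": int(a + b + c + d),
    }
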