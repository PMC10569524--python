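"""Connectivity-map-style transcriptomic-reversal scoring.

A disease signature query is the list of most-downregulated genes (up to 150)
of a differential-expression table.  Each compound in a reference library of
genes x compounds differential-expression z-scores is scored with a weighted
Kolmogorov-Smirnov enrichment statistic of the query genes in the compound's
ranked signature; the sign is flipped so that down-query genes concentrated
among a compound's most UPregulated genes (i.e. reversal) score negative.
Raw scores are normalized within same-sign compounds and converted to a
signed in-library percentile tau in [-100, 100]; compounds with tau < -90 are
reversal candidates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def extract_down_signature(detable: pd.DataFrame, k: int = 150,
                           significant_only: bool = False) -> list[str]:
    """Top-k downregulated genes, most negative log2FC first.

    Ties are broken lexicographically by gene id for determinism.  With
    ``significant_only`` the pool is restricted to significant genes.
    """
    t = detable
    if significant_only:
        t = t[t["significant"]]
    down = t[t["log2fc"] < 0]
    if len(down) == 0:
        raise ValueError("no downregulated genes to build a signature from")
    down = down.sort_values(["log2fc", "gene"], ascending=[True, True])
    return down["gene"].head(k).tolist()


def pseudo_bulk_de(adata, **kwargs) -> pd.DataFrame:
    """Differential expression over all cells pooled, ignoring cell type."""
    from .de import de_table
    return de_table(adata, population=None, **kwargs)


def rank_signature(z: pd.Series) -> pd.Series:
    """Sort one compound's z-vector descending, ties broken by gene id."""
    df = pd.DataFrame({"z": z.to_numpy(dtype=float), "gene": z.index.to_numpy()})
    df = df.sort_values(["z", "gene"], ascending=[False, True])
    return pd.Series(df["z"].to_numpy(), index=df["gene"].to_numpy())


def weighted_ks_es(query: list[str], ranked: pd.Series,
                   weight_exponent: float = 1.0) -> float:
    """GSEA-style weighted KS enrichment score of the query in a ranked signature.

    The running sum gains |z|^w / N_R at query-gene positions and loses
    1/(N - N_hits) at misses; the enrichment score is the running-sum value
    at its maximal absolute deviation, in [-1, 1].  Exponent 0 recovers the
    classic unweighted KS statistic.
    """
    if len(query) == 0:
        raise ValueError("empty query")
    missing = set(query) - set(ranked.index)
    if missing:
        raise ValueError(f"query genes absent from signature: {sorted(missing)[:5]}")
    hit = np.isin(ranked.index.to_numpy(), list(query))
    n = len(ranked)
    n_h = int(hit.sum())
    if n_h == n:
        return 1.0
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    n_r = w[hit].sum()
    steps = np.where(hit, np.where(n_r > 0, w / max(n_r, 1e-300), 0.0),
                     -1.0 / (n - n_h))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def connectivity_scores(query: list[str], z: pd.DataFrame,
                        weight_exponent: float = 1.0,
                        candidate_tau: float = -90.0) -> pd.DataFrame:
    """Score every compound of a reference set against one down-gene query.

    raw = -ES so that reversal is negative; ncs = raw / mean(|raw|) over
    compounds of the same sign; tau = sign(ncs) * 100 * fraction of compounds
    with strictly smaller |ncs|.  Candidate iff tau < candidate_tau.
    """
    if z.shape[1] < 2:
        raise ValueError("need at least 2 compounds for normalization")
    raw = np.empty(z.shape[1])
    for jj, comp in enumerate(z.columns):
        ranked = rank_signature(z[comp])
        raw[jj] = -weighted_ks_es(query, ranked, weight_exponent)

    ncs = np.zeros_like(raw)
    pos = raw > 0
    neg = raw < 0
    if pos.any():
        ncs[pos] = raw[pos] / np.abs(raw[pos]).mean()
    if neg.any():
        ncs[neg] = raw[neg] / np.abs(raw[neg]).mean()

    n = len(ncs)
    abs_ncs = np.abs(ncs)
    frac_smaller = np.array([(abs_ncs < a).sum() / n for a in abs_ncs])
    tau = np.sign(ncs) * 100.0 * frac_smaller

    out = pd.DataFrame({
        "compound": z.columns,
        "es": -raw,
        "raw": raw,
        "ncs": ncs,
        "tau": tau,
        "candidate": tau < candidate_tau,
    }).set_index("compound")
    return out.sort_values(["tau", "compound"])


def compare_candidate_lists(a: pd.DataFrame, b: pd.DataFrame,
                            compound_meta: pd.DataFrame | None = None,
                            top_k: int = 20) -> dict:
    """Overlap report between two candidate lists (sorted ascending by tau).

    Reports sizes, intersection, intersection as integer % of each list,
    top-k intersection, and per-list class composition when metadata with a
    "class" column is supplied.
    """
    list_a = a[a["candidate"]].sort_values(["tau", a.index.name or "compound"]).index.tolist()
    list_b = b[b["candidate"]].sort_values(["tau", b.index.name or "compound"]).index.tolist()
    inter = set(list_a) & set(list_b)
    top_a = a.sort_values("tau").head(top_k).index.tolist()
    top_b = b.sort_values("tau").head(top_k).index.tolist()
    top_inter = set(top_a) & set(top_b)

    def pct(num, den):
        return int(round(100.0 * num / den)) if den else 0

    report = {
        "n_candidates_a": len(list_a),
        "n_candidates_b": len(list_b),
        "n_overlap": len(inter),
        "overlap_pct_of_a": pct(len(inter), len(list_a)),
        "overlap_pct_of_b": pct(len(inter), len(list_b)),
        "top_k": top_k,
        "top_k_overlap": len(top_inter),
        "top_k_overlap_compounds": sorted(top_inter),
    }
    if compound_meta is not None and "class" in compound_meta.columns:
        for name, top in (("a", top_a), ("b", top_b)):
            classes = compound_meta.loc[top, "class"].value_counts(normalize=True)
            report[f"top_class_composition_{name}"] = {
                k: round(100.0 * v, 1) for k, v in classes.items()}
    return report
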