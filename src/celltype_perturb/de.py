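"""Two-part (hurdle) differential expression per gene per cell population.

The model follows the single-cell hurdle convention: a logistic regression of
the detection indicator and a Gaussian linear model of log-normalized
expression in detected cells, both with intercept, centered detection rate
(cdr, "ngeneson") and optionally sex as nuisance covariates.  Genotype is
tested by a likelihood-ratio test summing the two component deviances, with
degrees of freedom equal to the number of non-degenerate components, followed
by Benjamini-Hochberg FDR within the population.

Fold changes are reported as log2 of the ratio of CP10K group means with a
small pseudomean, so that the significance threshold of 0.14 log2
units corresponds to a 10% difference in means.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

_MAX_ABS_COEF = 15.0  # larger fitted logits indicate separation -> degenerate


@dataclass
class ComponentFit:
    ll_full: float
    ll_reduced: float
    ok: bool  # False -> degenerate, contributes 0 to the LRT with 0 df
    coef_full: np.ndarray | None = None


@dataclass
class HurdleFit:
    discrete: ComponentFit
    continuous: ComponentFit


def _logistic_loglik(X: np.ndarray, y: np.ndarray,
                     max_iter: int = 50, tol: float = 1e-9):
    """IRLS logistic fit; returns (loglik, coef, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    ybar = y.mean()
    beta[0] = np.log(ybar / (1.0 - ybar)) if 0.0 < ybar < 1.0 else 0.0
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            return -np.inf, beta, False
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    ll = float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))
    return ll, beta, converged


def _gaussian_loglik(X: np.ndarray, y: np.ndarray):
    """Profile Gaussian log-likelihood of an OLS fit (MLE variance).

    Returns (loglik, coef, rank).
    """
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    n = len(y)
    rss = float(resid @ resid)
    if rss <= 1e-12 * max(1.0, float(y @ y)):
        return np.inf, coef, rank
    sigma2 = rss / n
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return ll, coef, rank


def fit_hurdle(y: np.ndarray, X_full: np.ndarray,
               X_reduced: np.ndarray) -> HurdleFit:
    """Fit both hurdle components for one gene.

    ``y`` is the log-normalized expression per cell (zeros = undetected);
    ``X_full`` contains the genotype column, ``X_reduced`` drops it.
    """
    detected = y > 0

    # discrete component: logistic regression of the detection indicator
    d = detected.astype(float)
    if d.min() == d.max():
        disc = ComponentFit(0.0, 0.0, ok=False)
    else:
        llf, bf, okf = _logistic_loglik(X_full, d)
        llr, _, okr = _logistic_loglik(X_reduced, d)
        ok = (okf and okr and np.isfinite(llf) and np.isfinite(llr)
              and np.max(np.abs(bf)) < _MAX_ABS_COEF)
        disc = ComponentFit(llf, llr, ok=ok, coef_full=bf)

    # continuous component: Gaussian linear model on detected cells only
    Xd_full = X_full[detected]
    Xd_red = X_reduced[detected]
    yd = y[detected]
    if len(yd) <= X_full.shape[1]:
        cont = ComponentFit(0.0, 0.0, ok=False)
    else:
        llf, cf, rank_f = _gaussian_loglik(Xd_full, yd)
        llr, _, rank_r = _gaussian_loglik(Xd_red, yd)
        # no extra parameter actually estimable (e.g. genotype constant among
        # detected cells) or an exact fit -> degenerate
        ok = np.isfinite(llf) and np.isfinite(llr) and rank_f > rank_r
        cont = ComponentFit(llf, llr, ok=ok, coef_full=cf)

    return HurdleFit(discrete=disc, continuous=cont)


def lrt_genotype(fit: HurdleFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of genotype: summed component deviances vs chi2.

    Returns (statistic, df, p); df = number of non-degenerate components.
    A df of 0 means the gene is untested (p = nan).
    """
    stat = 0.0
    df = 0
    for comp in (fit.discrete, fit.continuous):
        if comp.ok:
            stat += max(0.0, 2.0 * (comp.ll_full - comp.ll_reduced))
            df += 1
    if df == 0:
        return 0.0, 0, np.nan
    return stat, df, float(stats.chi2.sf(stat, df))


def log2_fold_change(cp10k: np.ndarray, genotype: np.ndarray,
                     eps: float = 0.1) -> float:
    """log2((mean CP10K in HET + eps) / (mean CP10K in WT + eps)).

    Means are taken over all cells including zeros; the pseudomean eps keeps
    the ratio finite for weakly expressed genes.
    """
    het = genotype == "HET"
    wt = genotype == "WT"
    if not het.any() or not wt.any():
        raise ValueError("both genotypes must be present")
    m_het = float(cp10k[het].mean())
    m_wt = float(cp10k[wt].mean())
    return float(np.log2((m_het + eps) / (m_wt + eps)))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _design_matrices(obs: pd.DataFrame, sex_covariate: bool):
    n = len(obs)
    cols = [np.ones(n), obs["cdr"].to_numpy(dtype=float)]
    if sex_covariate:
        cols.append((obs["sex"].to_numpy() == "F").astype(float))
    X_reduced = np.column_stack(cols)
    genotype = (obs["genotype"].to_numpy() == "HET").astype(float)
    X_full = np.column_stack(cols + [genotype])
    return X_full, X_reduced


def cp10k_matrix(adata: ad.AnnData) -> sp.csc_matrix:
    """Counts rescaled to 10,000 per cell (no log), as a CSC matrix."""
    X = sp.csr_matrix(adata.X, dtype=float)
    total = np.asarray(X.sum(axis=1)).ravel()
    if (total <= 0).any():
        raise ValueError("cells with zero total counts")
    return X.multiply(1e4 / total[:, None]).tocsc()


def de_table(adata: ad.AnnData, population: str | None,
             sex_covariate: bool = True, lfc_min: float = 0.14,
             fdr_max: float = 0.05, min_cells_detected: int = 3,
             eps: float = 0.1) -> pd.DataFrame:
    """Hurdle differential expression for one population (or pooled if None).

    Requires a "lognorm" layer and the "cdr" obs column.  Genes carrying the
    excluded-class flag (non-coding / ribosomal / pseudogene proxies) are
    absent from the output.  FDR is computed within the population over tested
    genes; a gene is significant iff |log2FC| >= lfc_min and FDR < fdr_max.
    """
    if population is not None:
        sub = adata[adata.obs["cell_type"] == population]
        if sub.n_obs == 0:
            raise ValueError(f"population {population!r} not present")
    else:
        sub = adata
    obs = sub.obs
    genotypes = set(obs["genotype"].unique())
    if not {"WT", "HET"} <= set(map(str, genotypes)):
        raise ValueError("both genotypes must be present in the population")

    keep = ~sub.var.get("exclude_class", pd.Series(False, index=sub.var_names)).astype(bool)
    genes = sub.var_names[keep.to_numpy()]

    X_full, X_reduced = _design_matrices(obs, sex_covariate)
    lognorm = sp.csc_matrix(sub.layers["lognorm"])
    cp10k = cp10k_matrix(sub)
    genotype = obs["genotype"].to_numpy().astype(str)
    n_wt = int((genotype == "WT").sum())
    n_het = int((genotype == "HET").sum())

    gene_idx = sub.var_names.get_indexer(genes)
    records = []
    n_cells = sub.n_obs
    for g, j in zip(genes, gene_idx):
        y = np.asarray(lognorm[:, j].todense()).ravel()
        c = np.asarray(cp10k[:, j].todense()).ravel()
        lfc = log2_fold_change(c, genotype, eps=eps)
        n_det = int((y > 0).sum())
        if n_det < min_cells_detected:
            records.append((g, lfc, np.nan, False, 0, n_det))
            continue
        fit = fit_hurdle(y, X_full, X_reduced)
        statistic, df, p = lrt_genotype(fit)
        tested = df > 0
        records.append((g, lfc, p, tested, df, n_det))

    tbl = pd.DataFrame(records, columns=["gene", "log2fc", "p", "tested",
                                         "component_df", "n_detected"])
    tbl["population"] = population if population is not None else "pseudo_bulk"
    tbl["n_cells_wt"] = n_wt
    tbl["n_cells_het"] = n_het
    tbl["direction"] = np.where(tbl["log2fc"] < 0, "down", "up")
    tbl["fdr"] = np.nan
    tested_mask = tbl["tested"].to_numpy()
    if tested_mask.any():
        tbl.loc[tested_mask, "fdr"] = bh_fdr(tbl.loc[tested_mask, "p"].to_numpy())
    tbl["significant"] = (tested_mask
                          & (tbl["fdr"].to_numpy() < fdr_max)
                          & (np.abs(tbl["log2fc"].to_numpy()) >= lfc_min))
    tbl.attrs["population"] = tbl["population"].iloc[0] if len(tbl) else population
    tbl.attrs["lfc_min"] = lfc_min
    tbl.attrs["fdr_max"] = fdr_max
    tbl.attrs["covariates"] = ("cdr", "sex") if sex_covariate else ("cdr",)
    tbl.attrs["n_cells"] = n_cells
    return tbl


def apply_thresholds(tbl: pd.DataFrame, lfc_min: float,
                     fdr_max: float) -> pd.DataFrame:
    """Re-flag significance of an existing DE table under other thresholds.

    P-values and FDR are unchanged (the relaxed cut only moves the
    significance thresholds, e.g. FDR < 0.1 with a 5% expression change).
    """
    out = tbl.copy()
    tested = out["tested"].to_numpy()
    out["significant"] = (tested
                          & (out["fdr"].to_numpy() < fdr_max)
                          & (np.abs(out["log2fc"].to_numpy()) >= lfc_min))
    out.attrs.update(tbl.attrs)
    out.attrs["lfc_min"] = lfc_min
    out.attrs["fdr_max"] = fdr_max
    return out


def gene_wilcoxon_reduction(adata: ad.AnnData, gene: str) -> tuple[float, float]:
    """Percent expression reduction in mutants plus a rank-sum p-value.

    Reduction = 100 * (1 - mean_HET / mean_WT) on CP10K means; p from a
    two-sided Wilcoxon rank-sum on the log-normalized values.
    """
    if gene not in adata.var_names:
        raise KeyError(gene)
    j = adata.var_names.get_loc(gene)
    genotype = adata.obs["genotype"].to_numpy().astype(str)
    cp10k = np.asarray(cp10k_matrix(adata)[:, j].todense()).ravel()
    m_wt = cp10k[genotype == "WT"].mean()
    m_het = cp10k[genotype == "HET"].mean()
    if m_wt == 0:
        raise ValueError("WT mean expression is zero; reduction undefined")
    reduction = 100.0 * (1.0 - m_het / m_wt)
    y = np.asarray(sp.csc_matrix(adata.layers["lognorm"])[:, j].todense()).ravel()
    res = stats.mannwhitneyu(y[genotype == "HET"], y[genotype == "WT"],
                             alternative="two-sided")
    return float(reduction), float(res.pvalue)
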