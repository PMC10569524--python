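"""Bespoke phenotype statistics for the two-group longitudinal assays.

Includes the permutation-calibrated Mann-Whitney U procedure (pool both
groups, recompute the MWU p-value over label permutations, and report the
fraction of permuted p-values strictly below the observed one), trial
averaging with latency cutoffs, the integrated-RMS electroconvulsive stimulus,
relative qPCR quantification with technical-replicate filtering, and a
Mendelian-ratio chi-square.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

EXACT_POOL_MAX = 12  # exact U enumeration up to this pooled sample size


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Exact enumeration when the pooled sample is small (<= 12) and tie-free,
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= EXACT_POOL_MAX and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@lru_cache(maxsize=128)
def _exact_u_pvalues(nx: int, ny: int) -> np.ndarray:
    """Two-sided exact p-value for each possible U value (tie-free null).

    Built by subset-sum enumeration over the ranks 1..nx+ny; p(U) =
    min(1, 2 * min(P(U' <= U), P(U' >= U))).
    """
    n = nx + ny
    max_u = nx * ny
    # ways[k][s]: subsets of size k of {1..n} with rank sum s
    max_s = nx * n
    ways = np.zeros((nx + 1, max_s + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, nx), 0, -1):
            ways[k, r:] += ways[k - 1, :-r] if r > 0 else ways[k - 1]
    smin = nx * (nx + 1) // 2
    counts = ways[nx, smin:smin + max_u + 1]
    total = counts.sum()
    cdf = np.cumsum(counts) / total
    sf = np.cumsum(counts[::-1])[::-1] / total  # P(U >= u), point included
    return np.minimum(1.0, 2.0 * np.minimum(cdf, sf))


def _p_from_rank_sums(s, nx: int, ny: int, ranks: np.ndarray,
                      exact: bool) -> np.ndarray:
    """Two-sided MWU p-values from x-group rank sums (vectorized).

    Under label permutation of a fixed pool the tie pattern is constant, so
    for the asymptotic branch only the rank sum varies between permutations.
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    u = s - nx * (nx + 1) / 2.0
    if exact:
        table = _exact_u_pvalues(nx, ny)
        return table[np.round(u).astype(int)]
    n = nx + ny
    mean = nx * ny / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    if var <= 0:
        return np.ones_like(u)
    z = np.maximum(np.abs(u - mean) - 0.5, 0.0) / np.sqrt(var)
    return np.minimum(1.0, 2.0 * stats.norm.sf(z))


def permuted_mwu_p(x, y, n_perm: int = 10000, seed: int = 0
                   ) -> tuple[float, bool]:
    """Permutation-calibrated MWU p-value.

    Pools both groups, draws ``n_perm`` label permutations preserving group
    sizes, and reports the fraction of permuted MWU p-values strictly below
    the observed one.  When no permuted p falls below, the floor 1/n_perm is
    returned with ``is_floor_bound=True`` (reported as "< 1/n_perm").
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    pool = np.concatenate([x, y])
    ranks = stats.rankdata(pool)
    exact = (nx + ny <= EXACT_POOL_MAX
             and len(np.unique(pool)) == len(pool))

    p_obs = float(_p_from_rank_sums(ranks[:nx].sum(), nx, ny, ranks, exact)[0])

    rng = np.random.default_rng(seed)
    arr = np.tile(ranks, (n_perm, 1))
    rng.permuted(arr, axis=1, out=arr)
    perm_s = arr[:, :nx].sum(axis=1)
    perm_p = _p_from_rank_sums(perm_s, nx, ny, ranks, exact)

    count = int((perm_p < p_obs).sum())
    if count == 0:
        return 1.0 / n_perm, True
    return count / n_perm, False


def average_trials(trials, cutoff: float | None = 30.0,
                   min_value: float | None = None) -> float:
    """Clip each trial to [min_value, cutoff] and average.

    Failed trials are scored at the cutoff by the scoring convention, so a
    recorded value above the cutoff saturates there.
    """
    trials = np.asarray(trials, dtype=float)
    if trials.size == 0:
        raise ValueError("at least one trial is required")
    lo = -np.inf if min_value is None else min_value
    hi = np.inf if cutoff is None else cutoff
    return float(np.clip(trials, lo, hi).mean())


def irms(frequency_hz: float, pulse_width_ms: float, duration_s: float,
         amplitude_ma: float, sqrt_whole_product: bool = False) -> float:
    """Integrated root-mean-square electroconvulsive stimulus.

    Default reading: sqrt(frequency) * pulse_width * duration * amplitude
    (square root applied to frequency only, the literal operator order); the
    alternative grouping sqrt(frequency * width * duration * amplitude) is
    available behind ``sqrt_whole_product``.
    """
    vals = (frequency_hz, pulse_width_ms, duration_s, amplitude_ma)
    if any(v < 0 for v in vals):
        raise ValueError("all stimulus parameters must be nonnegative")
    if any(v == 0 for v in vals[:3]):
        raise ValueError("frequency, pulse width and duration must be positive")
    if sqrt_whole_product:
        return float(np.sqrt(frequency_hz * pulse_width_ms * duration_s
                             * amplitude_ma))
    return float(np.sqrt(frequency_hz) * pulse_width_ms * duration_s
                 * amplitude_ma)


def filter_ct_replicates(cts, sd_threshold: float = 0.3) -> np.ndarray:
    """Single-pass technical-replicate filter.

    If the replicate SD exceeds the threshold, drop replicates more than one
    SD from the replicate mean; otherwise keep all.
    """
    cts = np.asarray(cts, dtype=float)
    if len(cts) < 2:
        raise ValueError("at least technical duplicates are required")
    sd = float(np.std(cts, ddof=1))
    if sd <= sd_threshold:
        return cts
    mean = cts.mean()
    return cts[np.abs(cts - mean) <= sd]


def qpcr_ddct(ct_table: pd.DataFrame, target: str, reference: str,
              sd_threshold: float = 0.3) -> pd.DataFrame:
    """Relative quantification (ddCt) with replicate filtering.

    ``ct_table`` is long format with columns sample, genotype, gene, ct.
    Per (sample, gene) the replicate filter is applied; samples with fewer
    than 2 surviving replicates for either gene are excluded.  Then
    dCt = meanCt(target) - meanCt(reference), ddCt = dCt - mean(dCt over WT
    samples in the batch), RQ = 2**(-ddCt).
    """
    rows = []
    for (sample, gene), grp in ct_table.groupby(["sample", "gene"], sort=True):
        kept = filter_ct_replicates(grp["ct"].to_numpy(), sd_threshold)
        if len(kept) < 2:
            continue
        rows.append((sample, str(grp["genotype"].iloc[0]), gene,
                     float(kept.mean()), len(kept)))
    means = pd.DataFrame(rows, columns=["sample", "genotype", "gene",
                                        "mean_ct", "n_replicates"])
    wide = means.pivot_table(index=["sample", "genotype"], columns="gene",
                             values="mean_ct").reset_index()
    wide = wide.dropna(subset=[g for g in (target, reference) if g in wide.columns])
    if target not in wide.columns or reference not in wide.columns or not len(wide):
        raise ValueError("no samples with both target and reference retained")
    wide["delta_ct"] = wide[target] - wide[reference]
    wt = wide.loc[wide["genotype"] == "WT", "delta_ct"]
    if len(wt) == 0:
        raise ValueError("no WT samples in the batch to baseline against")
    wide["delta_delta_ct"] = wide["delta_ct"] - wt.mean()
    wide["rq"] = 2.0 ** (-wide["delta_delta_ct"])
    return wide[["sample", "genotype", "delta_ct", "delta_delta_ct", "rq"]]


def mendelian_chi_square(observed, expected_ratio) -> tuple[float, int, float]:
    """Pearson chi-square of observed genotype counts against an expected ratio.

    ``expected_ratio`` is normalized to proportions (e.g. intercross 1:2:1);
    returns (chi2, df, p) with df = categories - 1.
    """
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.sum() <= 0:
        raise ValueError("observed total must be positive")
    if (ratio < 0).any() or ratio.sum() <= 0:
        raise ValueError("expected ratio must be nonnegative with positive sum")
    props = ratio / ratio.sum()
    if (props == 0).any():
        raise ValueError("zero expected category")
    expected = props * obs.sum()
    chi2, p = stats.chisquare(obs, expected)
    return float(chi2), len(obs) - 1, float(p)


def phenotype_report(table: pd.DataFrame, measure: str, n_perm: int = 10000,
                     seed: int = 0) -> pd.DataFrame:
    """Permuted MWU p-value per timepoint for one measure of a phenotype table."""
    sub = table[table["measure"] == measure]
    if not len(sub):
        raise ValueError(f"measure {measure!r} not found")
    rows = []
    for i, (tp, grp) in enumerate(sub.groupby("timepoint", sort=True)):
        x = grp.loc[grp["genotype"] == "WT", "value"].to_numpy()
        y = grp.loc[grp["genotype"] == "HET", "value"].to_numpy()
        u, p = mann_whitney_u(x, y)
        p_perm, floor = permuted_mwu_p(x, y, n_perm=n_perm, seed=seed + i)
        rows.append((measure, tp, len(x), len(y), u, p, p_perm, floor))
    return pd.DataFrame(rows, columns=["measure", "timepoint", "n_wt", "n_het",
                                       "U", "p_mwu", "p_permuted",
                                       "is_floor_bound"])
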