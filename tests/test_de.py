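"""Hurdle-model differential expression: component fits against independent
oracles, LRT behaviour, fold-change arithmetic, and BH FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import celltype_perturb as cp
from celltype_perturb.de import (ComponentFit, HurdleFit, _gaussian_loglik,
                                 _logistic_loglik)


def _hurdle_data(rng, n=300, genotype_effect=0.0):
    cdr = rng.normal(0, 0.1, n)
    sex = rng.integers(0, 2, n).astype(float)
    gt = np.repeat([0.0, 1.0], n // 2)
    X_full = np.column_stack([np.ones(n), cdr, sex, gt])
    X_red = X_full[:, :3]
    detect_p = 1.0 / (1.0 + np.exp(-(0.3 + 2.0 * cdr + genotype_effect * gt)))
    det = rng.random(n) < detect_p
    y = np.zeros(n)
    y[det] = np.abs(rng.normal(1.5 + 0.5 * cdr[det] + genotype_effect * gt[det],
                               0.5)) + 1e-3
    return y, X_full, X_red


class TestComponentFits:
    def test_continuous_matches_ols_oracle(self, rng):
        """The continuous part on detected cells is an OLS fit: coefficients
        must agree with statsmodels OLS on the same rows to 1e-8."""
        import statsmodels.api as sm
        y, X_full, X_red = _hurdle_data(rng, genotype_effect=0.4)
        fit = cp.fit_hurdle(y, X_full, X_red)
        det = y > 0
        oracle = sm.OLS(y[det], X_full[det]).fit()
        np.testing.assert_allclose(fit.continuous.coef_full, oracle.params,
                                   atol=1e-8)

    def test_logistic_loglik_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        y, X_full, _ = _hurdle_data(rng)
        d = (y > 0).astype(float)
        ll, beta, ok = _logistic_loglik(X_full, d)
        assert ok
        oracle = sm.Logit(d, X_full).fit(disp=0)
        assert abs(ll - oracle.llf) < 1e-6
        np.testing.assert_allclose(beta, oracle.params, atol=1e-6)

    def test_gaussian_loglik_matches_numeric_optimizer(self, rng):
        """Closed-form profile Gaussian log-likelihood agrees with direct
        numeric maximization over (coefficients, sigma) to 1e-6."""
        y, X_full, _ = _hurdle_data(rng, n=80)
        det = y > 0
        Xd, yd = X_full[det], y[det]
        ll, coef, _ = _gaussian_loglik(Xd, yd)

        def negll(params):
            beta, log_sigma = params[:-1], params[-1]
            sigma = np.exp(log_sigma)
            resid = yd - Xd @ beta
            return 0.5 * len(yd) * np.log(2 * np.pi * sigma**2) \
                + 0.5 * (resid @ resid) / sigma**2

        x0 = np.concatenate([coef + 0.1, [0.0]])
        res = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000})
        assert abs(ll - (-res.fun)) < 1e-6

    def test_fully_detected_gene_reduces_to_continuous_df1(self, rng):
        y, X_full, X_red = _hurdle_data(rng)
        y[y == 0] = 0.5  # every cell detected
        fit = cp.fit_hurdle(y, X_full, X_red)
        assert not fit.discrete.ok
        _, df, p = cp.lrt_genotype(fit)
        assert df == 1
        assert np.isfinite(p)

    def test_null_p_uniform(self, rng):
        """With zero genotype coefficient in the generating two-part model,
        the LRT p-value is uniform (KS test at alpha = 0.01)."""
        ps = []
        for _ in range(400):
            y, X_full, X_red = _hurdle_data(rng, n=300, genotype_effect=0.0)
            _, df, p = cp.lrt_genotype(cp.fit_hurdle(y, X_full, X_red))
            if df > 0:
                ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestLrt:
    def test_both_degenerate_untested(self):
        fit = HurdleFit(ComponentFit(0, 0, ok=False), ComponentFit(0, 0, ok=False))
        stat, df, p = cp.lrt_genotype(fit)
        assert df == 0 and np.isnan(p)

    def test_zero_statistic_gives_p_one(self):
        fit = HurdleFit(ComponentFit(-5.0, -5.0, ok=True),
                        ComponentFit(-9.0, -9.0, ok=True))
        stat, df, p = cp.lrt_genotype(fit)
        assert stat == 0.0 and df == 2 and p == 1.0

    def test_invariant_to_cdr_rescaling(self, rng):
        y, X_full, X_red = _hurdle_data(rng, genotype_effect=0.5)
        s1, _, p1 = cp.lrt_genotype(cp.fit_hurdle(y, X_full, X_red))
        X_full2, X_red2 = X_full.copy(), X_red.copy()
        X_full2[:, 1] = 3.0 * X_full2[:, 1] + 7.0
        X_red2[:, 1] = 3.0 * X_red2[:, 1] + 7.0
        s2, _, p2 = cp.lrt_genotype(cp.fit_hurdle(y, X_full2, X_red2))
        assert abs(s1 - s2) < 1e-5
        assert abs(p1 - p2) < 1e-7


class TestLog2FoldChange:
    def test_equal_means_zero(self):
        vals = np.array([1.0, 2.0, 1.0, 2.0])
        gt = np.array(["WT", "WT", "HET", "HET"])
        assert cp.log2_fold_change(vals, gt) == 0.0

    def test_arithmetic(self):
        vals = np.array([10.0, 10.0, 5.0, 5.0])
        gt = np.array(["WT", "WT", "HET", "HET"])
        got = cp.log2_fold_change(vals, gt, eps=0.1)
        assert abs(got - np.log2(5.1 / 10.1)) < 1e-12

    def test_ten_percent_difference_is_014(self):
        # HET mean = 1.102 x WT mean with WT mean >> eps
        vals = np.array([1000.0, 1102.0])
        gt = np.array(["WT", "HET"])
        got = cp.log2_fold_change(vals, gt, eps=0.1)
        assert abs(got - 0.14) < 0.001

    def test_missing_genotype_rejected(self):
        with pytest.raises(ValueError):
            cp.log2_fold_change(np.array([1.0, 2.0]), np.array(["WT", "WT"]))


class TestBhFdr:
    def test_single_p_passthrough(self):
        np.testing.assert_allclose(cp.bh_fdr([0.03]), [0.03])

    def test_step_up_example(self):
        np.testing.assert_allclose(cp.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_order_invariance(self, rng):
        p = rng.random(50)
        perm = rng.permutation(50)
        q = cp.bh_fdr(p)
        q_perm = cp.bh_fdr(p[perm])
        np.testing.assert_allclose(q[perm], q_perm)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(5):
            p = rng.random(200)
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(cp.bh_fdr(p), q_ref, atol=1e-12)

    def test_empty_input(self):
        assert len(cp.bh_fdr([])) == 0


class TestDeTable:
    def test_genotype_swap_negates_lfc_keeps_p(self, null_sim):
        adata, _, _ = null_sim
        tbl = cp.de_table(adata, "pop01")
        flipped = adata.copy()
        gt = flipped.obs["genotype"].astype(str)
        flipped.obs["genotype"] = pd.Categorical(
            np.where(gt == "WT", "HET", "WT"), categories=["WT", "HET"])
        tbl2 = cp.de_table(flipped, "pop01")
        np.testing.assert_allclose(tbl["log2fc"], -tbl2["log2fc"], atol=1e-10)
        both = tbl["tested"] & tbl2["tested"]
        np.testing.assert_allclose(tbl.loc[both, "p"], tbl2.loc[both, "p"],
                                   atol=1e-6)

    def test_null_sim_false_positive_count_bounded(self, null_sim):
        adata, _, _ = null_sim
        tbl = cp.de_table(adata, "pop01")
        n_tested = int(tbl["tested"].sum())
        # FDR < 0.05 plus the fold-change gate: expect at most a handful
        assert tbl["significant"].sum() <= max(2, 0.1 * 0.05 * n_tested)

    def test_below_lfc_threshold_not_significant(self):
        # a record with log2fc -0.10 and fdr 0.01 fails the 0.14 gate
        tbl = pd.DataFrame({"gene": ["g1"], "log2fc": [-0.10], "p": [0.001],
                            "tested": [True], "fdr": [0.01]})
        out = cp.apply_thresholds(tbl, lfc_min=0.14, fdr_max=0.05)
        assert not out["significant"].iloc[0]
        relaxed = cp.apply_thresholds(tbl, lfc_min=0.0704, fdr_max=0.1)
        assert relaxed["significant"].iloc[0]

    def test_planted_halving_recovered_with_sign_and_magnitude(self):
        """Downregulation planted at log2FC -1.11 (a ~50% reduction) with
        300 cells per genotype is recovered with the correct sign and a
        typical estimate error under 0.3 log2 units."""
        from celltype_perturb.config import SimConfig
        cfg = SimConfig(seed=11, n_cell_types=2, cells_per_type_per_genotype=300,
                        n_genes=1000, frac_de_vulnerable=0.06, frac_de_other=0.0,
                        lfc_mean=1.11, lfc_sd=1e-6, down_bias=1.0,
                        vulnerable_type="pop01")
        adata, truth = cp.simulate_counts(cfg)
        adata = cp.qc_pipeline(adata, min_genes=50)
        tbl = cp.de_table(adata, "pop01")
        down = truth.planted_genes("pop01").merge(tbl, on="gene")
        assert len(down) > 30
        assert (down["log2fc"] < 0).all()
        err = np.abs(down["log2fc"] - down["true_log2fc"])
        assert err.median() < 0.3

    def test_missing_population_rejected(self, null_sim):
        adata, _, _ = null_sim
        with pytest.raises(ValueError):
            cp.de_table(adata, "no_such_population")

    def test_excluded_class_genes_absent(self, null_sim):
        adata, _, _ = null_sim
        tbl = cp.de_table(adata, "pop01")
        excluded = set(adata.var_names[adata.var["exclude_class"]])
        assert not (set(tbl["gene"]) & excluded)


class TestWilcoxonReduction:
    def test_arithmetic_identity(self, rng):
        import anndata as ad
        import scipy.sparse as sp
        wt = rng.poisson(10.0, 200)
        het = rng.poisson(10.0, 200)
        counts = np.column_stack([np.concatenate([wt, het]),
                                  np.full(400, 50)])
        a = ad.AnnData(
            X=sp.csr_matrix(counts),
            obs=pd.DataFrame({
                "genotype": ["WT"] * 200 + ["HET"] * 200},
                index=[f"c{i}" for i in range(400)]),
            var=pd.DataFrame(index=["target", "ballast"]))
        cp.normalize_cp10k_log(a)
        red, p = cp.gene_wilcoxon_reduction(a, "target")
        # same distribution: reduction near 0 and p not extreme
        assert abs(red) < 15
        assert p > 1e-4

    def test_26_percent_reduction(self):
        import anndata as ad
        import scipy.sparse as sp
        # equal cell totals so CP10K preserves the raw 74:100 ratio exactly
        counts = np.column_stack([
            np.concatenate([np.full(50, 100), np.full(50, 74)]),
            np.concatenate([np.full(50, 900), np.full(50, 926)])])
        a = ad.AnnData(
            X=sp.csr_matrix(counts),
            obs=pd.DataFrame({"genotype": ["WT"] * 50 + ["HET"] * 50},
                             index=[f"c{i}" for i in range(100)]),
            var=pd.DataFrame(index=["target", "ballast"]))
        cp.normalize_cp10k_log(a)
        red, p = cp.gene_wilcoxon_reduction(a, "target")
        assert abs(red - 26.0) < 1e-9

    def test_ranksum_p_matches_enumeration_oracle(self, rng):
        """The two-sided rank-sum p equals full enumeration of all
        C(n_x + n_y, n_x) orderings for small tie-free samples."""
        for _ in range(5):
            x = rng.normal(0, 1, 5)
            y = rng.normal(0.8, 1, 4)
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact")
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            u_obs = ranks[:5].sum() - 5 * 6 / 2
            us = []
            for comb in itertools.combinations(range(9), 5):
                us.append(ranks[list(comb)].sum() - 5 * 6 / 2)
            us = np.array(us)
            p_enum = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
            assert abs(res.pvalue - p_enum) < 1e-12
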