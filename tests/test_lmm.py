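"""Mixed-model core: oracles, limits and invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from revmark.lmm import (
    Model,
    _BatchedREML,
    build_design,
    fit_all_genes,
    fit_lmm_reml,
    satterthwaite_test,
)

from conftest import paired_samples


def _paired_data(rng, n, tau=2.0, sigma=1.0, effect=0.7):
    samples = paired_samples(n, rng)
    cbt = (samples["timepoint"] == "T10M").to_numpy(dtype=float)
    y = np.repeat(rng.normal(0, tau, n), 2) + rng.normal(0, sigma, 2 * n) + effect * cbt
    return samples, y


class TestPairedOracle:
    """Balanced pairs with equal weights must reproduce the paired t-test."""

    def test_matches_paired_t_closed_form(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(4, 16))
            samples, y = _paired_data(rng, n)
            design = build_design(samples, None, Model.CBT)
            fit = fit_lmm_reml(y, design, np.ones(2 * n))
            if fit.boundary:
                continue
            t, df, p = satterthwaite_test(fit, 1)
            diffs = y[1::2] - y[0::2]
            tt = stats.ttest_1samp(diffs, 0)
            assert fit.beta[1] == pytest.approx(diffs.mean(), abs=1e-10)
            assert np.sqrt(fit.cov_beta[1, 1]) == pytest.approx(
                diffs.std(ddof=1) / np.sqrt(n), abs=1e-10
            )
            assert df == pytest.approx(n - 1, abs=1e-8)
            assert p == pytest.approx(tt.pvalue, abs=1e-10)

    def test_worked_three_patient_example(self):
        # within-pair differences (1, 2, 3); baselines spread apart so the
        # random-intercept variance is estimated in the interior (identical
        # baselines would land exactly on the tau^2 = 0 boundary, where the
        # paired t-test correspondence degenerates for any mixed-model fit)
        samples = paired_samples(3)
        y = np.array([10.0, 11.0, 20.0, 22.0, 30.0, 33.0])
        design = build_design(samples, None, Model.CBT)
        fit = fit_lmm_reml(y, design, np.ones(6))
        t, df, p = satterthwaite_test(fit, 1)
        assert fit.beta[1] == pytest.approx(2.0, abs=1e-10)
        assert df == pytest.approx(2.0, abs=1e-4)
        assert t == pytest.approx(2.0 / (1.0 / np.sqrt(3)), abs=1e-6)
        assert p == pytest.approx(0.0742, abs=2e-4)


class TestAgainstLmerTest:
    """Frozen oracle: a weighted unbalanced-covariate fit checked against
    the reference mixed-model implementation (lme4/lmerTest, R)."""

    Y = [-0.900306738584, -0.109089439798, 0.041867161252, 1.076800322107,
         0.136908339434, 0.38293375841, -0.049772396514, 1.011615956717,
         -0.259833756614, -0.069353092652, 0.693345567236, 1.347122661653,
         0.62857359346, 0.947489012353, 0.536843749984, 1.521174389129,
         0.53955459693, 0.797223511855, 0.004745579827, 0.876646440156]
    W = [0.811572669528, 0.650788064406, 1.58440330081, 0.912655242437,
         2.108497785643, 1.480310180955, 2.548231129356, 2.190715775406,
         1.143389931732, 2.547101463767, 2.472863765241, 1.346191623381,
         1.078485880612, 2.142737860732, 0.677331705745, 0.839752146683,
         0.319878128328, 2.424695819256, 2.095097312798, 2.203946522291]
    CTG = [189, 723, 630, 462, 457, 789, 187, 663, 277, 193]
    # reference values from lmerTest::summary on the same data
    EXPECTED = {
        "intercept": (-0.301271474243, 0.3402075798, 8.69313330, 0.399691335384),
        "cbt": (0.665289512836, 0.1136424421, 8.87597980, 0.000255853177),
        "ctg_per100": (0.087307509759, 0.0650707202, 7.79816342, 0.217438422270),
    }

    def test_coefficients_and_satterthwaite(self):
        samples = paired_samples(10, ctg=self.CTG)
        design = build_design(samples, None, Model.CTG)
        fit = fit_lmm_reml(np.array(self.Y), design, np.array(self.W))
        assert fit.tau2 == pytest.approx(0.17599044844, rel=1e-6)
        assert fit.sigma2 == pytest.approx(0.09267677092, rel=1e-6)
        assert fit.reml_loglik == pytest.approx(-13.46758, abs=1e-4)
        for j, name in enumerate(design.colnames):
            beta, se, df, p = self.EXPECTED[name]
            t, df_hat, p_hat = satterthwaite_test(fit, j)
            assert fit.beta[j] == pytest.approx(beta, abs=1e-8)
            assert np.sqrt(fit.cov_beta[j, j]) == pytest.approx(se, abs=1e-8)
            assert df_hat == pytest.approx(df, abs=1e-5)
            assert p_hat == pytest.approx(p, abs=1e-8)


class TestREMLOptimum:
    def test_profiled_optimum_beats_dense_grid(self):
        rng = np.random.default_rng(5)
        grid = np.r_[0.0, np.geomspace(1e-6, 1e4, 999)]
        for _ in range(10):
            n = int(rng.integers(4, 10))
            samples, y = _paired_data(rng, n, tau=rng.uniform(0, 2))
            design = build_design(samples, None, Model.CBT)
            eng = _BatchedREML(y[None, :], np.ones((1, 2 * n)), design.matrix, design.groups)
            theta, ll, _ = eng.optimize()
            best_grid = max(
                eng.profiled_loglik(np.array([t]))[0] for t in grid
            )
            assert ll[0] >= best_grid - 1e-6

    def test_boundary_reduces_to_wls(self):
        # independent errors: tau^2 truth is 0, the fit should hit the
        # boundary and match weighted least squares
        rng = np.random.default_rng(9)
        for _ in range(5):
            n = 6
            samples = paired_samples(n, rng)
            design = build_design(samples, None, Model.CBT)
            y = rng.normal(0, 1, 2 * n)
            # remove all between-pair mean variation so the REML estimate
            # of the intercept variance is driven to the zero boundary
            y = y - np.repeat((y[::2] + y[1::2]) / 2, 2)
            y += design.matrix[:, 1] * 0.3
            w = rng.uniform(0.5, 2.0, 2 * n)
            fit = fit_lmm_reml(y, design, w)
            assert fit.boundary
            X = design.matrix
            WX = X * w[:, None]
            beta_wls = np.linalg.solve(X.T @ WX, WX.T @ y)
            assert np.allclose(fit.beta, beta_wls, atol=1e-8)
            t, df, p = satterthwaite_test(fit, 1)
            assert df == pytest.approx(2 * n - 2, abs=1e-6)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(21)
        samples, y = _paired_data(rng, 8)
        design = build_design(samples, None, Model.CBT)
        w = rng.uniform(0.5, 2, 16)
        f1 = fit_lmm_reml(y, design, w)
        c = 3.7
        f2 = fit_lmm_reml(c * y, design, w)
        assert np.allclose(f2.beta, c * f1.beta, rtol=1e-8)
        assert f2.sigma2 == pytest.approx(c**2 * f1.sigma2, rel=1e-6)
        assert f2.tau2 == pytest.approx(c**2 * f1.tau2, rel=1e-6)
        t1, df1, p1 = satterthwaite_test(f1, 1)
        t2, df2, p2 = satterthwaite_test(f2, 1)
        assert t2 == pytest.approx(t1, abs=1e-8)
        assert df2 == pytest.approx(df1, abs=1e-6)
        assert p2 == pytest.approx(p1, abs=1e-8)

    def test_half_weight_duplicate_keeps_gls_coefficients(self):
        # splitting one observation into two half-weight copies leaves the
        # GLS coefficient map at any fixed variance ratio unchanged
        rng = np.random.default_rng(3)
        n = 6
        groups = np.repeat(np.arange(n), 2)
        X = np.column_stack([np.ones(2 * n), np.tile([0.0, 1.0], n)])
        y = np.repeat(rng.normal(0, 1, n), 2) + rng.normal(0, 0.7, 2 * n)
        w = rng.uniform(0.5, 2, 2 * n)
        y2 = np.r_[y, y[0]]
        w2 = np.r_[w, w[0] / 2]
        w2[0] = w[0] / 2
        X2 = np.vstack([X, X[0]])
        g2 = np.r_[groups, groups[0]]
        e1 = _BatchedREML(y[None, :], w[None, :], X, groups)
        e2 = _BatchedREML(y2[None, :], w2[None, :], X2, g2)
        for theta in (0.0, 0.3, 2.0):
            # the engines normalise weights to mean one, so the raw-scale
            # variance ratio theta maps to theta * mean(weights) internally
            b1 = e1._core(np.array([theta * e1.w_scale[0]]))[2][0]
            b2 = e2._core(np.array([theta * e2.w_scale[0]]))[2][0]
            assert np.allclose(b1, b2, atol=1e-10)


class TestDesigns:
    def test_ctg_scaling_and_response_zero_at_baseline(self):
        samples = paired_samples(3, ctg=[400, 200, 800])
        d = build_design(samples, None, Model.CTG)
        col = d.matrix[:, 2]
        assert col[0] == col[1] == 4.0
        scores = pd.DataFrame(
            {"patient_id": ["P00", "P01", "P02"], "compound_response": [1.2, -0.5, 0.0]}
        )
        d2 = build_design(samples, scores, Model.RESPONSE)
        resp = d2.matrix[:, 2]
        assert resp[0] == 0.0 and resp[1] == 1.2
        assert resp[2] == 0.0 and resp[3] == -0.5

    def test_all_zero_scores_is_rank_deficient(self):
        samples = paired_samples(3)
        scores = pd.DataFrame(
            {"patient_id": ["P00", "P01", "P02"], "compound_response": [0.0, 0.0, 0.0]}
        )
        with pytest.raises(ValueError, match="rank"):
            build_design(samples, scores, Model.RESPONSE)

    def test_missing_score_named(self):
        samples = paired_samples(2)
        scores = pd.DataFrame({"patient_id": ["P00"], "compound_response": [1.0]})
        with pytest.raises(ValueError, match="P01"):
            build_design(samples, scores, Model.RESPONSE)

    def test_unpaired_patient_rejected(self):
        samples = paired_samples(3).iloc[:-1]
        with pytest.raises(ValueError, match="P02"):
            build_design(samples, None, Model.CBT)


class TestFitAllGenes:
    def test_gene_order_permutation(self, small_cohort):
        expr = small_cohort["expr"]
        res = fit_all_genes(expr, small_cohort["samples"], None, Model.CBT)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(expr.gene_ids))
        from revmark.prep import WeightedExpression

        expr_p = WeightedExpression(
            [expr.gene_ids[i] for i in perm],
            expr.sample_ids,
            expr.logcpm[perm],
            expr.weights[perm],
        )
        res_p = fit_all_genes(expr_p, small_cohort["samples"], None, Model.CBT)
        merged = res.merge(res_p, on="gene_id", suffixes=("_a", "_b"))
        assert np.allclose(merged["coef_a"], merged["coef_b"], atol=1e-10)
        assert np.allclose(merged["p_a"], merged["p_b"], atol=1e-10)

    def test_fold_change_is_two_to_coef(self, small_results):
        res = small_results["cbt"]
        assert np.allclose(res["fold_change"], 2.0 ** res["coef"])

    def test_cbt_effect_recovery(self, small_cohort, small_results):
        truth = small_cohort["truth"]
        res = small_results["cbt"].set_index("gene_id")
        tg = truth.gene_frame().set_index("gene_id")
        planted = [g for g in truth.cbt_set if g in res.index]
        err = res.loc[planted, "coef"] - tg.loc[planted, "cbt_effect"]
        assert abs(err.mean()) < 0.1
        assert np.corrcoef(res.loc[planted, "coef"], tg.loc[planted, "cbt_effect"])[0, 1] > 0.95

    def test_misaligned_samples_rejected(self, small_cohort):
        samples = small_cohort["samples"].iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="misaligned"):
            fit_all_genes(small_cohort["expr"], samples, None, Model.CBT)
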