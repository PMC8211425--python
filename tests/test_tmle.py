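"""Targeted learning: Super Learner stacking and the TMLE estimator."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import tmecausal as tc
from tmecausal.tmle import (
    SuperLearner,
    TMLEConfig,
    marginal_odds_ratio,
    tmle_estimate,
)


def _confounded(n, rng, beta=-1.0):
    z = rng.binomial(1, 0.5, n)
    G = rng.binomial(1, expit(-0.3 + 1.0 * z))
    p1 = expit(-0.5 + beta + 1.0 * z)
    p0 = expit(-0.5 + 1.0 * z)
    Y = rng.binomial(1, np.where(G == 1, p1, p0))
    true_ae = float((p1 - p0).mean())
    return Y, G, z[:, None], z, true_ae


class TestSuperLearner:
    def test_single_learner_is_identity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 2))
        y = rng.binomial(1, expit(X[:, 0]))
        sl = SuperLearner(("glm",), seed=0).fit(X, y)
        from sklearn.linear_model import LogisticRegression
        ref = LogisticRegression(C=np.inf, max_iter=1000).fit(X, y)
        assert np.allclose(sl.predict_proba(X),
                           np.clip(ref.predict_proba(X)[:, 1], 1e-6, 1 - 1e-6))
        assert sl.weights_ == {"glm": 1.0}

    def test_weights_form_convex_combination(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 3))
        y = rng.binomial(1, expit(X[:, 0] - 0.5 * X[:, 1]))
        sl = SuperLearner(("glm", "glmnet", "random_forest"),
                          v_folds=5, seed=3).fit(X, y)
        w = np.array(list(sl.weights_.values()))
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_recovers_logistic_truth(self):
        rng = np.random.default_rng(4)
        n = 2000
        X = rng.normal(size=(n, 2))
        p = expit(0.3 + 0.8 * X[:, 0] - 0.6 * X[:, 1])
        y = rng.binomial(1, p)
        sl = SuperLearner(("glm", "glmnet", "xgboost"), v_folds=5, seed=5).fit(X, y)
        mse = float(np.mean((sl.predict_proba(X) - p) ** 2))
        assert mse < 0.01
        # the stack is never worse than the worst library member in CV loss
        from tmecausal.tmle import _nll
        stack_nll = _nll(sl.predict_proba(X), y)
        assert stack_nll <= max(sl.cv_nll_.values())

    def test_no_features_predicts_mean(self):
        y = np.array([0, 0, 1, 1, 1])
        sl = SuperLearner(("glm",)).fit(np.empty((5, 0)), y)
        assert np.allclose(sl.predict_proba(np.empty((5, 0))), 0.6)


class TestMarginalOddsRatio:
    def test_equal_means_give_unity(self):
        assert marginal_odds_ratio(0.3, 0.3) == pytest.approx(1.0)

    def test_direct_value(self):
        assert marginal_odds_ratio(0.5, 0.25) == pytest.approx(3.0)

    @pytest.mark.parametrize("a,b", [(0.1, 0.9), (0.4, 0.2), (0.73, 0.08)])
    def test_reciprocal_symmetry(self, a, b):
        assert marginal_odds_ratio(a, b) * marginal_odds_ratio(b, a) == \
            pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("a,b", [(0.0, 0.5), (0.5, 1.0)])
    def test_boundary_rejected(self, a, b):
        with pytest.raises(ValueError):
            marginal_odds_ratio(a, b)


class TestTMLE:
    def test_randomized_null(self):
        rng = np.random.default_rng(11)
        n = 5000
        W = rng.normal(size=(n, 1))
        G = rng.binomial(1, 0.5, n)
        Y = rng.binomial(1, 0.4, n)
        est = tmle_estimate(Y, G, W, TMLEConfig(learners=("glm",), seed=1))
        assert abs(est.ae) < 2 * est.ae_se
        assert est.mor_ci95[0] < 1.0 < est.mor_ci95[1]

    def test_saturated_q_matches_gcomputation(self):
        rng = np.random.default_rng(12)
        Y, G, W, z, _ = _confounded(3000, rng)
        q0 = np.where(z == 1, Y[(G == 0) & (z == 1)].mean(),
                      Y[(G == 0) & (z == 0)].mean())
        q1 = np.where(z == 1, Y[(G == 1) & (z == 1)].mean(),
                      Y[(G == 1) & (z == 0)].mean())
        g_true = expit(-0.3 + 1.0 * z)
        est = tmle_estimate(Y, G, W, TMLEConfig(learners=("glm",)),
                            q_init=(q0, q1), g_init=g_true)
        gcomp = float((q1 - q0).mean())
        assert est.ae == pytest.approx(gcomp, abs=1e-4)

    def test_plugin_identities_and_score_equation(self):
        rng = np.random.default_rng(13)
        Y, G, W, _, _ = _confounded(800, rng)
        est = tmle_estimate(Y, G, W, TMLEConfig(learners=("glm",), seed=2))
        assert est.ae == est.ie.mean()
        assert est.ae == pytest.approx(est.ey1 - est.ey0, abs=1e-15)
        assert est.mor == marginal_odds_ratio(est.ey1, est.ey0)
        assert abs(est.diagnostics["mean_ic"]) <= 1e-8

    def test_double_robustness(self):
        rng = np.random.default_rng(14)
        n = 10_000
        Y, G, W, z, true_ae = _confounded(n, rng)
        g_true = expit(-0.3 + 1.0 * z)
        q_bad = (np.full(n, Y.mean()), np.full(n, Y.mean()))
        q_good = (expit(-0.5 + 1.0 * z), expit(-1.5 + 1.0 * z))
        g_bad = np.full(n, G.mean())
        est_q_bad = tmle_estimate(Y, G, W, q_init=q_bad, g_init=g_true)
        est_g_bad = tmle_estimate(Y, G, W, q_init=q_good, g_init=g_bad)
        assert abs(est_q_bad.ae - true_ae) < 3 * est_q_bad.ae_se
        assert abs(est_g_bad.ae - true_ae) < 3 * est_g_bad.ae_se

    def test_one_armed_exposure_rejected(self):
        with pytest.raises(ValueError, match="positivity"):
            tmle_estimate(np.array([0, 1, 0]), np.array([1, 1, 1]), None)

    def test_nonbinary_exposure_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            tmle_estimate(np.array([0, 1]), np.array([0.3, 1.0]), None)


class TestRunPerGene:
    def test_empty_candidates_empty_table(self, small_cohort):
        _, counts, clinical, _ = small_cohort
        clin, cts, outcome = tc.filter_samples(clinical, counts)
        pool = pd.DataFrame({"age": clin["age"].to_numpy()})
        table, fits = tc.run_per_gene([], cts, pool, outcome.y, {})
        assert len(table) == 0 and fits == {}

    def test_batch_order_invariance(self, small_cohort):
        _, counts, clinical, truth = small_cohort
        clin, cts, outcome = tc.filter_samples(clinical, counts)
        pool = pd.DataFrame({
            "stage_adv": clin["stage_adv"].to_numpy(),
            "age": clin["age"].to_numpy()})
        genes = [truth.exposure_gene, cts.index[0]]
        sets = {g: ["stage_adv", "age"] for g in genes}
        cfg = tc.TMLEConfig(learners=("glm",), seed=9)
        t1, _ = tc.run_per_gene(genes, cts, pool, outcome.y, sets, cfg)
        t2, _ = tc.run_per_gene(genes[::-1], cts, pool, outcome.y, sets, cfg)
        merged = t1.set_index("gene").join(t2.set_index("gene"),
                                           rsuffix="_rev")
        assert np.allclose(merged["AE"], merged["AE_rev"])
        assert np.allclose(merged["MOR"], merged["MOR_rev"])

    def test_causal_and_null_gene_distinguished(self, small_cohort):
        _, counts, clinical, truth = small_cohort
        clin, cts, outcome = tc.filter_samples(clinical, counts)
        pool = pd.DataFrame({
            "stage_adv": clin["stage_adv"].to_numpy(),
            "age": clin["age"].to_numpy()})
        null_gene = next(
            g for g, m in truth.signature_membership.items()
            if m == "none" and g != truth.exposure_gene)
        genes = [truth.exposure_gene, null_gene]
        sets = {g: ["stage_adv", "age"] for g in genes}
        table, _ = tc.run_per_gene(genes, cts, pool, outcome.y, sets,
                                   tc.TMLEConfig(learners=("glm",), seed=3))
        causal = table.set_index("gene").loc[truth.exposure_gene]
        null = table.set_index("gene").loc[null_gene]
        assert causal["AE_ci_high"] < 0  # CI excludes 0, correct sign
        assert null["AE_ci_low"] < 0 < null["AE_ci_high"]
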