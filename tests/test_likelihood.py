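"""Exact likelihood and closed-form profile maximisation."""

import numpy as np
import pytest

import ordercause as oc
from ordercause.likelihood import SIGMA_FLOOR, ProfileLikelihood

from _oracles import brute_force_max_loglik, conditional_loglik, finite_diff_grad
from conftest import random_dag


def make_dataset(p=3, n=8, n_ko=2, sigma=0.2, seed=0):
    rng = np.random.default_rng(seed)
    dag = random_dag(p, rng)
    params = oc.GbnParams(dag=dag, m=rng.normal(0.5, 0.2, p), sigma=np.full(p, sigma))
    assignments = [{} for _ in range(n - n_ko)] + [
        {dag.labels[rng.integers(p)]: 0.0} for _ in range(n_ko)
    ]
    data = oc.sample_gbn(params, oc.InterventionDesign(assignments=assignments), seed=seed + 1)
    return params, data


class TestLogLikelihood:
    def test_single_gene_reduces_to_univariate_gaussian(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 0.5, size=20)
        dag = oc.WeightedDag(labels=["g"], W=np.zeros((1, 1)))
        m, s = 0.8, 0.6
        params = oc.GbnParams(dag=dag, m=[m], sigma=[s])
        data = oc.ExpressionDataset(
            X=x[:, None], design=oc.InterventionDesign.observational(20), labels=["g"]
        )
        expected = (
            -10 * np.log(2 * np.pi) - 20 * np.log(s) - ((x - m) ** 2).sum() / (2 * s**2)
        )
        assert oc.log_likelihood(params, data) == pytest.approx(expected, rel=1e-12)

    def test_fully_clamped_gene_contributes_nothing(self):
        params, _ = make_dataset(p=2, n=6, n_ko=0, seed=3)
        design = oc.InterventionDesign(assignments=[{"v1": 0.0}] * 6)
        data = oc.sample_gbn(params, design, seed=4)
        base = oc.log_likelihood(params, data)
        # change sigma of the always-clamped gene: likelihood unchanged
        other = oc.GbnParams(dag=params.dag, m=params.m, sigma=params.sigma * [1.0, 7.0])
        assert oc.log_likelihood(other, data) == base

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_conditional_density_oracle(self, seed):
        params, data = make_dataset(seed=seed)
        assert oc.log_likelihood(params, data) == pytest.approx(
            conditional_loglik(params, data), rel=1e-10
        )

    def test_nonpositive_sigma_rejected(self):
        params, data = make_dataset()
        bad = oc.GbnParams(dag=params.dag, m=params.m, sigma=params.sigma)
        bad.sigma = bad.sigma.copy()
        bad.sigma[0] = -0.1
        with pytest.raises(ValueError):
            oc.log_likelihood(bad, data)


class TestProfileMean:
    def test_w_zero_gives_clampfree_column_means(self):
        params, data = make_dataset(p=3, n=12, n_ko=4, seed=5)
        m = oc.profile_mean(data, np.zeros((3, 3)))
        mask, _ = data.design.clamp_arrays(data.labels)
        for j in range(3):
            rows = ~mask[:, j]
            assert m[j] == pytest.approx(data.X[rows, j].mean())

    def test_noiseless_recovers_true_means(self, chain3):
        params = oc.GbnParams(dag=chain3, m=[0.5, -0.2, 1.0], sigma=[1e-12] * 3)
        data = oc.sample_gbn(params, oc.InterventionDesign.observational(6), seed=0)
        m = oc.profile_mean(data, chain3.W)
        assert np.allclose(m, [0.5, -0.2, 1.0], atol=1e-9)

    def test_gradient_vanishes_at_optimum(self):
        params, data = make_dataset(seed=7)
        order = params.dag.topological_order
        W, _ = oc.profile_weights(data, order)
        m_hat = oc.profile_mean(data, W)
        sigma_hat = oc.profile_sigma(data, W)

        def ll_of_m(m):
            pr = oc.GbnParams(dag=oc.WeightedDag(labels=data.labels, W=W), m=m, sigma=sigma_hat)
            return oc.log_likelihood(pr, data)

        g = finite_diff_grad(ll_of_m, m_hat)
        assert np.all(np.abs(g) < 1e-6 * max(1.0, abs(ll_of_m(m_hat))))


class TestProfileWeights:
    def test_consistency_recovers_true_weights(self):
        rng = np.random.default_rng(21)
        dag = random_dag(4, rng)
        params = oc.GbnParams(dag=dag, m=np.full(4, 0.5), sigma=np.full(4, 0.1))
        data = oc.sample_gbn(params, oc.InterventionDesign.observational(10_000), seed=22)
        W, deg = oc.profile_weights(data, dag.topological_order)
        assert not deg
        assert np.allclose(W[dag.W != 0], dag.W[dag.W != 0], atol=0.02)

    def test_first_node_has_no_parents(self):
        _, data = make_dataset(seed=9)
        order = np.array([2, 0, 1])
        W, _ = oc.profile_weights(data, order)
        assert np.all(W[:, 2] == 0)

    def test_duplicate_parents_flagged_degenerate(self):
        rng = np.random.default_rng(1)
        n = 30
        x1 = rng.normal(size=n)
        x3 = 0.5 * x1 + 0.05 * rng.normal(size=n)
        X = np.column_stack([x1, x1.copy(), x3])
        data = oc.ExpressionDataset(
            X=X, design=oc.InterventionDesign.observational(n), labels=["a", "b", "c"]
        )
        W, deg = oc.profile_weights(data, np.array([0, 1, 2]))
        assert ("a", "c") in deg and ("b", "c") in deg
        # minimum-norm solution splits the coefficient across the twins
        assert W[0, 2] == pytest.approx(W[1, 2], rel=1e-6)

    def test_rss_decreases_with_nested_parent_sets(self):
        _, data = make_dataset(p=4, n=20, n_ko=3, seed=13)
        s_small = oc.profile_sigma(data, oc.profile_weights(data, [0, 1, 3, 2])[0])
        s_large = oc.profile_sigma(data, oc.profile_weights(data, [0, 1, 2, 3])[0])
        # gene 3's parent candidates grow {0,1} -> {0,1,2}: residual shrinks
        assert s_large[3] <= s_small[3] + 1e-12


class TestProfileSigma:
    def test_noiseless_hits_floor(self, chain3):
        params = oc.GbnParams(dag=chain3, m=[0.5] * 3, sigma=[1e-14] * 3)
        data = oc.sample_gbn(params, oc.InterventionDesign.observational(8), seed=2)
        s = oc.profile_sigma(data, chain3.W)
        assert np.all(s >= SIGMA_FLOOR)
        assert s[0] == pytest.approx(SIGMA_FLOOR)

    def test_w_zero_population_sd(self):
        _, data = make_dataset(p=3, n=15, n_ko=0, seed=4)
        s = oc.profile_sigma(data, np.zeros((3, 3)))
        assert np.allclose(s, data.X.std(axis=0, ddof=0))

    def test_equals_rms_residual_of_weight_fit(self):
        _, data = make_dataset(p=4, n=25, n_ko=5, seed=6)
        order = np.array([1, 3, 0, 2])
        W, _ = oc.profile_weights(data, order)
        s = oc.profile_sigma(data, W)
        mask, _ = data.design.clamp_arrays(data.labels)
        for j in range(4):
            rows = ~mask[:, j]
            sub = data.X[rows]
            Y = sub - sub.mean(0)
            r = Y[:, j] - Y @ W[:, j]
            assert s[j] == pytest.approx(np.sqrt((r**2).mean()), rel=1e-9)


class TestMaxLogLikelihood:
    def test_observational_invariant_to_ordering(self):
        _, data = make_dataset(p=4, n=25, n_ko=0, seed=8)
        rng = np.random.default_rng(0)
        lls = [
            oc.max_log_likelihood(data, rng.permutation(4)).loglik for _ in range(12)
        ]
        assert np.max(lls) - np.min(lls) < 1e-8

    def test_matches_generic_optimizer(self):
        _, data = make_dataset(p=3, n=30, n_ko=6, sigma=0.3, seed=11)
        order = np.array([0, 1, 2])
        fit = oc.max_log_likelihood(data, order)
        oracle = brute_force_max_loglik(data, order, seed=1)
        assert fit.loglik >= oracle - 1e-7  # closed form cannot lose
        assert fit.loglik == pytest.approx(oracle, abs=1e-5)

    def test_true_ordering_beats_violating_ordering(self):
        skeleton = oc.benchmark_dag_skeleton()
        dag = oc.random_weights(skeleton, seed=30)
        params = oc.GbnParams(dag=dag, m=np.full(10, 0.5), sigma=np.full(10, 0.01))
        design, _ = oc.benchmark_design("mixed", seed=30)
        data = oc.sample_gbn(params, design, seed=31)
        good = oc.max_log_likelihood(data, dag.topological_order).loglik
        bad = oc.max_log_likelihood(data, dag.topological_order[::-1]).loglik
        assert good >= bad

    def test_loglik_recompute_matches(self):
        params, data = make_dataset(p=4, n=30, n_ko=5, seed=15)
        fit = oc.max_log_likelihood(data, params.dag.topological_order)
        assert oc.log_likelihood(fit.params, data) == pytest.approx(fit.loglik, abs=1e-8)

    def test_w_respects_ordering(self):
        _, data = make_dataset(p=5, n=20, n_ko=4, seed=16)
        order = np.array([3, 1, 4, 0, 2])
        fit = oc.max_log_likelihood(data, order)
        pos = np.empty(5, dtype=int)
        pos[order] = np.arange(5)
        ii, jj = np.nonzero(fit.params.dag.W)
        assert np.all(pos[ii] < pos[jj])

    def test_clamped_samples_do_not_touch_own_gene_estimates(self):
        params, data = make_dataset(p=3, n=20, n_ko=0, seed=17)
        order = params.dag.topological_order
        fit0 = oc.max_log_likelihood(data, order)
        j = data.labels[1]
        extra = oc.InterventionDesign(
            assignments=data.design.assignments + [{j: 0.0}] * 3
        )
        # clamp value propagates downstream but j's own estimates are
        # untouched because its clamped samples are excluded from K_j
        X2 = np.vstack([data.X, oc.sample_gbn(params, oc.InterventionDesign(assignments=[{j: 0.0}] * 3), seed=18).X])
        data2 = oc.ExpressionDataset(X=X2, design=extra, labels=data.labels)
        fit1 = oc.max_log_likelihood(data2, order)
        assert fit1.params.m[1] == pytest.approx(fit0.params.m[1], rel=1e-12)
        assert fit1.params.sigma[1] == pytest.approx(fit0.params.sigma[1], rel=1e-12)
        assert np.allclose(fit1.params.dag.W[:, 1], fit0.params.dag.W[:, 1])

    def test_fully_clamped_gene_undefined_but_usable(self):
        params, _ = make_dataset(p=3, n=10, n_ko=0, seed=19)
        lab = params.labels[0]
        design = oc.InterventionDesign(assignments=[{lab: 0.0}] * 10)
        data = oc.sample_gbn(params, design, seed=20)
        fit = oc.max_log_likelihood(data, params.dag.topological_order)
        assert lab in fit.undefined_genes
        assert np.isnan(fit.params.m[0])
        assert np.isfinite(fit.loglik)


class TestFastSlowAgreement:
    @pytest.mark.parametrize("design_name", ["mixed", "multiple_ko", "observational"])
    def test_vectorised_loglik_equals_per_node_path(self, design_name):
        skeleton = oc.benchmark_dag_skeleton()
        dag = oc.random_weights(skeleton, seed=40)
        params = oc.GbnParams(dag=dag, m=np.full(10, 0.5), sigma=np.full(10, 0.1))
        design, _ = oc.benchmark_design(design_name, seed=40)
        data = oc.sample_gbn(params, design, seed=41)
        pl = ProfileLikelihood(data)
        rng = np.random.default_rng(42)
        for _ in range(25):
            o = rng.permutation(10)
            assert pl.fit_loglik(o) == pytest.approx(pl._fit_arrays(o)[3], abs=1e-9)
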