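import numpy as np
import pytest

from hemoseg.cluster import MoMGInit
from hemoseg.mixture import (MoMGParams, PerfusionMixture, e_step,
                             log_gaussian_density, m_step, mdl_score, select_k)


def _random_spd(rng, w):
    a = rng.normal(size=(w, w))
    return a @ a.T + w * np.eye(w)


class TestLogGaussian:
    def test_univariate_standard_normal_at_zero(self):
        assert log_gaussian_density(np.array([0.0]), np.array([0.0]),
                                    np.array([[1.0]])) == pytest.approx(
            np.log(1 / np.sqrt(2 * np.pi)))

    def test_identity_covariance_at_mean(self):
        w = 6
        x = np.zeros(w)
        val = log_gaussian_density(x, x, np.eye(w))
        assert val == pytest.approx(-(w / 2) * np.log(2 * np.pi))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_naive_inverse_determinant_formula(self, seed):
        rng = np.random.default_rng(seed)
        w = int(rng.integers(2, 6))
        cov = _random_spd(rng, w)
        mean = rng.normal(size=w)
        x = rng.normal(size=(w, 7))
        naive = (-0.5 * (w * np.log(2 * np.pi) + np.log(np.linalg.det(cov))
                 + np.einsum("ij,jk,ik->i", (x - mean[:, None]).T,
                             np.linalg.inv(cov), (x - mean[:, None]).T)))
        np.testing.assert_allclose(log_gaussian_density(x, mean, cov), naive,
                                   rtol=1e-9)

    def test_extreme_values_stay_finite(self):
        val = log_gaussian_density(np.array([80.0]), np.array([0.0]),
                                   np.array([[1.0]]))
        assert np.isfinite(val) and val < -3000

    def test_non_spd_raises(self):
        with pytest.raises(ValueError):
            log_gaussian_density(np.zeros(2), np.zeros(2),
                                 np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestEStep:
    def test_single_component_full_responsibility(self, rng):
        Y = rng.normal(size=(2, 30))
        params = MoMGParams(np.array([1.0]), np.zeros((1, 2)),
                            np.eye(2)[None])
        post, ll = e_step(Y, params)
        np.testing.assert_allclose(post, 1.0)
        assert np.isfinite(ll)

    def test_symmetric_point_splits_evenly(self):
        params = MoMGParams(np.array([0.5, 0.5]),
                            np.array([[-1.0], [1.0]]),
                            np.array([[[1.0]], [[1.0]]]))
        post, _ = e_step(np.array([[0.0]]), params)
        np.testing.assert_allclose(post[:, 0], [0.5, 0.5])

    def test_matches_probability_space_on_benign_input(self, rng):
        w, K, n = 2, 3, 25
        Y = rng.normal(size=(w, n))
        props = np.array([0.2, 0.5, 0.3])
        means = rng.normal(size=(K, w))
        covs = np.stack([_random_spd(rng, w) for _ in range(K)])
        params = MoMGParams(props, means, covs)
        post, ll = e_step(Y, params)
        dens = np.stack([props[i] * np.exp(log_gaussian_density(
            Y, means[i], covs[i])) for i in range(K)])
        np.testing.assert_allclose(post, dens / dens.sum(axis=0), rtol=1e-9)
        assert ll == pytest.approx(np.log(dens.sum(axis=0)).sum())

    def test_underflow_never_produces_nan(self):
        params = MoMGParams(np.array([0.5, 0.5]),
                            np.array([[-500.0], [500.0]]),
                            np.array([[[1.0]], [[1.0]]]))
        post, ll = e_step(np.array([[0.0, 500.0, -500.0]]), params)
        assert np.all(np.isfinite(post)) and np.isfinite(ll)
        np.testing.assert_allclose(post.sum(axis=0), 1.0, atol=1e-9)


class TestMStep:
    def test_hard_posteriors_reduce_to_labeled_mle(self, rng):
        Y = rng.normal(size=(2, 40))
        labels = np.repeat([0, 1], 20)
        post = np.zeros((2, 40))
        post[labels, np.arange(40)] = 1.0
        params = m_step(Y, post, ridge=0.0)
        for k in range(2):
            sel = Y[:, labels == k]
            np.testing.assert_allclose(params.means[k], sel.mean(axis=1))
            dev = sel - sel.mean(axis=1, keepdims=True)
            np.testing.assert_allclose(params.covariances[k],
                                       dev @ dev.T / 20, atol=1e-12)
        np.testing.assert_allclose(params.proportions, [0.5, 0.5])

    def test_uniform_posteriors_give_global_moments(self, rng):
        Y = rng.normal(size=(3, 50))
        post = np.full((2, 50), 0.5)
        params = m_step(Y, post, ridge=0.0)
        np.testing.assert_allclose(params.means[0], params.means[1])
        np.testing.assert_allclose(params.means[0], Y.mean(axis=1))
        np.testing.assert_allclose(params.covariances[0],
                                   params.covariances[1])

    def test_vanishing_class_is_reseeded(self, rng):
        Y = rng.normal(size=(2, 30))
        post = np.vstack([np.ones(30), np.zeros(30)])
        params = m_step(Y, post)
        assert np.all(np.isfinite(params.means))
        assert np.all(np.linalg.eigvalsh(params.covariances[1]) > 0)
        assert params.proportions.sum() == pytest.approx(1.0)


def _simulate_mixture(rng, props, means, covs, n):
    K, w = means.shape
    counts = rng.multinomial(n, props)
    cols, labels = [], []
    for k in range(K):
        L = np.linalg.cholesky(covs[k])
        cols.append(means[k][:, None] + L @ rng.standard_normal((w, counts[k])))
        labels.append(np.full(counts[k], k))
    order = rng.permutation(n)
    return np.concatenate(cols, axis=1)[:, order], np.concatenate(labels)[order]


class TestEMFit:
    def test_init_at_mle_of_separable_data_converges_immediately(self, rng):
        means = np.array([[-6.0, 0.0], [6.0, 0.0]])
        covs = np.stack([np.eye(2)] * 2)
        Y, labels = _simulate_mixture(rng, [0.5, 0.5], means, covs, 400)
        post = np.zeros((2, 400))
        post[labels, np.arange(400)] = 1.0
        init = m_step(Y, post)
        res = PerfusionMixture(Y, 2).fit(init)
        assert res.n_iter <= 4 and res.converged
        match = (res.labels == labels).mean()
        assert max(match, 1 - match) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_loglik_monotone_from_random_init(self, seed):
        rng = np.random.default_rng(seed)
        Y = rng.normal(size=(3, 150)) + (rng.random((3, 150)) > 0.5) * 3
        res = PerfusionMixture(Y, 3).fit(initializer="random", seed=seed)
        assert np.all(np.diff(res.loglik_trace) > -1e-8)

    def test_identical_runs_identical_results(self, rng):
        Y = rng.normal(size=(2, 100))
        r1 = PerfusionMixture(Y, 3).fit(initializer="random", seed=5)
        r2 = PerfusionMixture(Y, 3).fit(initializer="random", seed=5)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        np.testing.assert_array_equal(r1.loglik_trace, r2.loglik_trace)

    def test_permuting_init_permutes_output(self, rng):
        Y = rng.normal(size=(2, 120)) + (rng.random((2, 120)) > 0.5) * 4
        init, _ = __import__("hemoseg.cluster", fromlist=["hc_init"]).hc_init(Y, 3)
        perm = np.array([2, 0, 1])
        init_p = MoMGInit(init.proportions[perm], init.means[perm],
                          init.covariances[perm])
        r = PerfusionMixture(Y, 3).fit(init)
        rp = PerfusionMixture(Y, 3).fit(init_p)
        assert r.loglik == pytest.approx(rp.loglik, rel=1e-9)
        # component j of the permuted fit is component perm[j] of the original
        np.testing.assert_array_equal(perm[rp.labels], r.labels)

    def test_parameter_recovery_against_sklearn(self):
        """Independent cross-check: same model fitted by sklearn's EM."""
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(12)
        props = np.array([0.3, 0.5, 0.2])
        means = np.array([[0.0, 0.0], [5.0, 1.0], [-2.0, 6.0]])
        covs = np.stack([np.eye(2), [[2.0, 0.5], [0.5, 1.0]], np.eye(2) * 0.5])
        Y, labels = _simulate_mixture(rng, props, means, covs, 6000)
        res = PerfusionMixture(Y, 3).fit()
        gm = GaussianMixture(3, means_init=res.params.means,
                             weights_init=res.params.proportions,
                             precisions_init=np.linalg.inv(res.params.covariances),
                             random_state=0).fit(Y.T)
        order_ours = np.argsort(res.params.means[:, 0])
        order_sk = np.argsort(gm.means_[:, 0])
        np.testing.assert_allclose(res.params.means[order_ours],
                                   gm.means_[order_sk], atol=0.05)
        np.testing.assert_allclose(np.sort(res.params.proportions),
                                   np.sort(gm.weights_), atol=0.01)
        # and both recover the truth within 3 standard errors
        n_k = 6000 * props
        se = np.sqrt(np.array([np.diag(c) for c in covs]) / n_k[:, None])
        order_true = np.argsort(means[:, 0])
        assert np.all(np.abs(res.params.means[order_ours] - means[order_true])
                      < 3 * se[order_true] + 0.02)


class TestMDL:
    def test_duplicated_component_raises_score(self, rng):
        Y = rng.normal(size=(2, 300))
        r1 = PerfusionMixture(Y, 1).fit()
        p = r1.params
        dup = MoMGInit(np.array([0.5, 0.5]),
                       np.vstack([p.means, p.means]),
                       np.stack([p.covariances[0]] * 2))
        r2 = PerfusionMixture(Y, 2).fit(dup, max_iter=0)
        assert r2.loglik == pytest.approx(r1.loglik, rel=1e-6)
        assert mdl_score(r2) > mdl_score(r1)

    def test_k1_score_finite(self, rng):
        res = PerfusionMixture(rng.normal(size=(2, 100)), 1).fit()
        assert np.isfinite(res.mdl)

    def test_free_parameter_count(self):
        p = MoMGParams(np.full(3, 1 / 3), np.zeros((3, 4)),
                       np.stack([np.eye(4)] * 3))
        assert p.n_free_parameters == 2 + 12 + 3 * 10

    def test_select_k_trivial_range(self, rng):
        Y = rng.normal(size=(2, 80))
        best, fits = select_k(Y, (2, 2))
        assert best == 2 and len(fits) == 1

    def test_select_k_finds_five_separated_components(self):
        rng = np.random.default_rng(4)
        means = np.array([[0, 0], [8, 0], [0, 8], [8, 8], [4, 16]], dtype=float)
        covs = np.stack([np.eye(2)] * 5)
        Y, _ = _simulate_mixture(rng, np.full(5, 0.2), means, covs, 2000)
        best, _ = select_k(Y, (3, 7), seed=0)
        assert best == 5


def test_summary_contains_key_fields(rng):
    res = PerfusionMixture(rng.normal(size=(2, 60)), 2).fit()
    text = res.summary()
    assert "MDL" in text and "log-likelihood" in text and "components" in text
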