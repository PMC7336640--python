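import numpy as np
import pytest

from qlcox import (
    FitControl,
    QuasiLinearParams,
    SurvivalDataset,
    fit_mle,
    init_params,
    observed_information,
    partial_log_likelihood,
    score,
    surrogate_G,
    surrogate_beta_gradient,
)
from qlcox.fitting import update_beta, update_pi

from _oracles import cox_newton_oracle, cox_loglik_grad_hess
from conftest import random_dataset, random_params


class TestSurrogate:
    def test_anchored_value_equals_loglik(self, small_data, small_params):
        assert surrogate_G(small_params, small_params, small_data) == pytest.approx(
            partial_log_likelihood(small_data, small_params), rel=1e-12)

    def test_minorizes_away_from_anchor(self, rng, small_data, small_params):
        # G(theta, theta0) <= l(theta) with equality at the anchor
        for _ in range(10):
            other = random_params(rng, K=2, p=2)
            assert surrogate_G(other, small_params, small_data) <= \
                partial_log_likelihood(small_data, other) + 1e-10

    def test_gradient_tangency(self, small_data, small_params):
        # d G / d theta at the anchor equals the score
        gpi, gbeta = score(small_data, small_params)
        gbeta_G = surrogate_beta_gradient(small_params, small_params, small_data)
        np.testing.assert_allclose(gbeta_G, gbeta, atol=1e-12)
        eps = 1e-6
        for m in range(small_params.K):
            for j in range(small_params.p):
                up, dn = small_params.beta.copy(), small_params.beta.copy()
                up[m, j] += eps
                dn[m, j] -= eps
                fd = (surrogate_G(small_params.with_beta(up), small_params, small_data)
                      - surrogate_G(small_params.with_beta(dn), small_params, small_data)
                      ) / (2 * eps)
                assert gbeta[m, j] == pytest.approx(fd, abs=1e-5)

    def test_beta_gradient_matches_fd_off_anchor(self, rng, small_data, small_params):
        other = random_params(rng, K=2, p=2)
        grad = surrogate_beta_gradient(other, small_params, small_data)
        eps = 1e-6
        for m in range(2):
            for j in range(2):
                up, dn = other.beta.copy(), other.beta.copy()
                up[m, j] += eps
                dn[m, j] -= eps
                fd = (surrogate_G(other.with_beta(up), small_params, small_data)
                      - surrogate_G(other.with_beta(dn), small_params, small_data)
                      ) / (2 * eps)
                assert grad[m, j] == pytest.approx(fd, abs=1e-5)


class TestUpdateBeta:
    def test_single_component_reaches_cox_mle(self, rng):
        d = random_dataset(rng, n=10, p=2)
        b_oracle, _, _ = cox_newton_oracle(d.time, d.event, d.covariates)
        # iterate the MM coefficient update to its fixed point
        params = QuasiLinearParams([1.0], np.zeros((1, 2)))
        for _ in range(200):
            new = update_beta(params, d)
            if np.abs(new - params.beta).max() < 1e-12:
                break
            params = params.with_beta(new)
        np.testing.assert_allclose(params.beta[0], b_oracle, atol=1e-6)

    def test_zero_covariates_keep_zero_solution(self, rng):
        d = SurvivalDataset(rng.uniform(1, 5, 8), np.ones(8, dtype=int),
                            np.zeros((8, 2)))
        params = random_params(rng, K=2, p=2)
        new = update_beta(params.with_beta(np.zeros((2, 2))), d)
        np.testing.assert_allclose(new, 0.0, atol=1e-12)

    def test_estimating_equation_residual(self, rng):
        # substituting the root back into the displayed equation
        d = random_dataset(rng, n=5, p=1, censor_frac=0.0)
        params = random_params(rng, K=2, p=1)
        new = update_beta(params, d)
        from qlcox.likelihood import Workspace
        ws = Workspace.build(d)
        p_s, pstar_s = ws.posteriors(params)
        for k in range(2):
            target = ((ws.delta * p_s[:, k])[:, None] * ws.X).sum(axis=0)
            logD = ws.log_risk_sum(ws.X @ params.beta[k])
            v = ws.X @ new[k]
            c, s0, s1, _ = ws.risk_moments(v, second=False)
            g = (ws.delta * pstar_s[:, k]) * np.exp(c + np.log(s0) - logD)
            rhs = (g / s0) @ s1
            assert np.abs(target - rhs).max() < 1e-8


class TestUpdatePi:
    def test_single_component_returns_one(self, rng):
        d = random_dataset(rng, n=8, p=2)
        params = random_params(rng, K=1, p=2)
        np.testing.assert_allclose(update_pi(params, d), [1.0])

    def test_symmetric_components_stay_symmetric(self, rng):
        d = random_dataset(rng, n=8, p=2)
        b = rng.normal(size=2)
        params = QuasiLinearParams([0.5, 0.5], np.vstack([b, b]))
        np.testing.assert_allclose(update_pi(params, d), [0.5, 0.5], atol=1e-12)

    def test_matches_direct_evaluation(self, rng):
        import math

        from _oracles import brute_posteriors, risk_set
        d = random_dataset(rng, n=5, p=1, censor_frac=0.0)
        params = random_params(rng, K=2, p=1)
        beta_new = update_beta(params, d)
        result = update_pi(params, d, beta_new=beta_new)
        p, pstar = brute_posteriors(d.time, d.event, d.covariates,
                                    params.pi, params.beta)
        unnorm = np.zeros(2)
        for k in range(2):
            num = sum(d.event[i] * p[k, i] for i in range(5))
            den = 0.0
            for i in range(5):
                R = risk_set(d.time, i)
                ratio = (sum(math.exp(float(d.covariates[l] @ beta_new[k])) for l in R)
                         / sum(math.exp(float(d.covariates[l] @ params.beta[k]))
                               for l in R))
                den += d.event[i] * pstar[k, i] * ratio
            unnorm[k] = params.pi[k] * num / den
        np.testing.assert_allclose(result, unnorm / unnorm.sum(), rtol=1e-10)

    def test_sums_to_one(self, rng):
        d = random_dataset(rng, n=12, p=2)
        params = random_params(rng, K=3, p=2)
        assert update_pi(params, d).sum() == pytest.approx(1.0, abs=1e-12)


class TestInitParams:
    def test_deterministic_given_seed(self, rng):
        d = random_dataset(rng, n=40, p=2)
        a = init_params(d, 2, seed=7)
        b = init_params(d, 2, seed=7)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.pi, b.pi)

    def test_single_component_uses_full_data(self, rng):
        d = random_dataset(rng, n=30, p=2, censor_frac=0.1)
        init = init_params(d, 1, seed=0)
        np.testing.assert_allclose(init.pi, [1.0])
        # light initialization ridge keeps this near, not at, the Cox MLE
        b_oracle, _, _ = cox_newton_oracle(d.time, d.event, d.covariates)
        np.testing.assert_allclose(init.beta[0], b_oracle, atol=0.05)

    def test_two_components_distinct_and_finite(self, scenario1_data):
        init = init_params(scenario1_data, 2, seed=3)
        assert np.all(np.isfinite(init.beta))
        assert not np.allclose(init.beta[0], init.beta[1])
        np.testing.assert_allclose(init.pi, [0.5, 0.5])


class TestFitMLE:
    def test_single_component_matches_cox_oracle(self, rng):
        d = random_dataset(rng, n=50, p=2, censor_frac=0.2)
        res = fit_mle(d, 1, FitControl(n_restarts=1))
        b_oracle, ll_oracle, _ = cox_newton_oracle(d.time, d.event, d.covariates)
        np.testing.assert_allclose(res.params.beta[0], b_oracle, atol=1e-5)
        assert res.loglik == pytest.approx(ll_oracle, abs=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_monotone_ascent(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(1, 4))
        p = int(rng.integers(1, 4))
        d = random_dataset(rng, n=60, p=p, censor_frac=0.25)
        res = fit_mle(d, K, FitControl(n_restarts=1, max_outer_iter=100, seed=seed))
        diffs = np.diff(res.trace)
        assert np.all(diffs >= -1e-8)

    def test_score_small_at_convergence(self, scenario1_data):
        # the MM iteration converges linearly, so the residual gradient
        # scales with the log-likelihood stopping tolerance
        res = fit_mle(scenario1_data, 2,
                      FitControl(n_restarts=1, seed=0, tol=1e-11,
                                 max_outer_iter=3000))
        gpi, gbeta = score(scenario1_data, res.params)
        # stationarity on the simplex tangent space: pi-gradient components
        # equalize; beta-gradient vanishes
        tangent = gpi * res.params.pi - res.params.pi * (gpi @ res.params.pi)
        assert np.abs(tangent).max() < 1e-2
        assert np.abs(gbeta).max() < 1e-2

    def test_permutation_invariant_optimum(self, scenario1_data):
        c = FitControl(n_restarts=2, seed=0)
        res = fit_mle(scenario1_data, 2, c)
        ll_perm = partial_log_likelihood(scenario1_data, res.params.permuted([1, 0]))
        assert ll_perm == pytest.approx(res.loglik, abs=1e-9)

    def test_restricted_fit_respects_mask(self, scenario1_data):
        res = fit_mle(scenario1_data, 2, FitControl(n_restarts=1),
                      groups=[[0], [1]])
        assert res.params.beta[0, 1] == 0.0
        assert res.params.beta[1, 0] == 0.0
        assert res.params.beta[0, 0] != 0.0


class TestObservedInformation:
    def test_symmetric(self, rng):
        d = random_dataset(rng, n=30, p=2)
        params = random_params(rng, K=2, p=2)
        info = observed_information(d, params)
        np.testing.assert_allclose(info, info.T, atol=1e-10)

    def test_single_component_matches_cox_information(self, rng):
        d = random_dataset(rng, n=30, p=2, censor_frac=0.2)
        res = fit_mle(d, 1, FitControl(n_restarts=1))
        info = observed_information(d, res.params)
        _, _, H_oracle = cox_loglik_grad_hess(d.time, d.event, d.covariates,
                                              res.params.beta[0])
        np.testing.assert_allclose(info, H_oracle, atol=1e-4)

    def test_matches_second_differences_of_loglik(self, rng):
        from qlcox.likelihood import _pack, _unpack

        d = random_dataset(rng, n=20, p=1)
        params = random_params(rng, K=2, p=1)
        info = observed_information(d, params)
        phi = _pack(params)
        h = 1e-4
        H_fd = np.zeros((phi.size, phi.size))
        for a in range(phi.size):
            for b in range(phi.size):
                pp = np.zeros((2, 2))
                for ia, sa in enumerate((h, -h)):
                    for ib, sb in enumerate((h, -h)):
                        q = phi.copy()
                        q[a] += sa
                        q[b] += sb
                        pp[ia, ib] = partial_log_likelihood(d, _unpack(q, params))
                H_fd[a, b] = (pp[0, 0] - pp[0, 1] - pp[1, 0] + pp[1, 1]) / (4 * h * h)
        np.testing.assert_allclose(info, -H_fd, atol=1e-4)
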