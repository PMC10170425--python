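"""LASSO solver oracles and network estimation behavior."""

import numpy as np
import pytest
from scipy import optimize

from clpnet import (
    EstimationConfig,
    SimulationConfig,
    apply_display_threshold,
    count_nonzero_edges,
    estimate_clpn,
    fit_node_lasso,
    lambda_max,
    lasso_fit,
    simulate_panel,
)
from clpnet._solver import cd_path, penalized_objective
from clpnet.estimation import CLPNetwork, EstimationError


def brute_force_lasso(X, y, alpha, x0=None):
    """Independent minimizer: split beta = u - v, u,v >= 0 makes the
    objective smooth with box constraints, solvable by L-BFGS-B."""
    n, p = X.shape
    Xc = X - X.mean(0)
    yc = y - y.mean()

    def fun(z):
        beta = z[:p] - z[p:]
        resid = yc - Xc @ beta
        grad_beta = -(Xc.T @ resid) / n
        f = resid @ resid / (2 * n) + alpha * z.sum()
        return f, np.concatenate([grad_beta + alpha, -grad_beta + alpha])

    z0 = np.zeros(2 * p) if x0 is None else np.concatenate([np.maximum(x0, 0), np.maximum(-x0, 0)])
    res = optimize.minimize(
        fun, z0, jac=True, method="L-BFGS-B",
        bounds=[(0, None)] * (2 * p),
        options={"maxiter": 20_000, "ftol": 1e-16, "gtol": 1e-12},
    )
    return res.x[:p] - res.x[p:]


def orthonormal_design(n, p, seed):
    """Centered X with X'X/n exactly the identity."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, p))
    A -= A.mean(0)
    Q, _ = np.linalg.qr(A)
    return Q * np.sqrt(n)


class TestLambdaMax:
    def test_orthogonal_outcome_gives_zero(self):
        X = orthonormal_design(40, 3, 0)
        y = np.zeros(40)
        with pytest.warns(UserWarning, match="zero variance"):
            assert lambda_max(X, y) == 0.0

    def test_single_predictor_equals_correlation(self):
        # standardized x and y with sample correlation r: lambda_max = |r|
        rng = np.random.default_rng(1)
        n = 20_000
        x = rng.standard_normal(n)
        y = 0.6 * x + rng.standard_normal(n) * np.sqrt(1 - 0.36)
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
        r = float(x @ y / n)
        assert lambda_max(x[:, None], y) == pytest.approx(abs(r), abs=1e-12)
        assert abs(r) == pytest.approx(0.6, abs=0.02)

    def test_fit_at_lambda_max_is_identically_zero(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 6))
        y = X @ rng.normal(size=6) + rng.standard_normal(100)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        lm = lambda_max(Xc, yc)
        assert np.all(lasso_fit(X, y, lm) == 0.0)
        assert np.all(lasso_fit(X, y, lm * 1.5) == 0.0)


class TestLassoFit:
    @pytest.mark.parametrize("seed", range(5))
    def test_unpenalized_limit_equals_ols(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 60, 5
        X = rng.standard_normal((n, p)) @ (np.eye(p) + 0.3)
        y = X @ rng.normal(size=p) + rng.standard_normal(n)
        beta = lasso_fit(X, y, 0.0)
        Xc = X - X.mean(0)
        ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
        np.testing.assert_allclose(beta, ols, atol=1e-6)

    def test_orthonormal_design_soft_threshold_closed_form(self):
        n, p = 200, 6
        X = orthonormal_design(n, p, 3)
        rng = np.random.default_rng(4)
        y = X @ np.array([0.9, -0.5, 0.3, -0.1, 0.05, 0.0]) + rng.standard_normal(n)
        yc = y - y.mean()
        b = X.T @ yc / n  # OLS under orthonormality
        for alpha in np.geomspace(1.0, 1e-4, 12):
            beta = lasso_fit(X, y, alpha)
            expected = np.sign(b) * np.maximum(np.abs(b) - alpha, 0.0)
            np.testing.assert_allclose(beta, expected, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_minimizer(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, p = 50, 5
        X = rng.standard_normal((n, p)) @ rng.standard_normal((p, p))
        y = X @ rng.normal(size=p) + rng.standard_normal(n)
        alpha = 0.1 * lambda_max(X - X.mean(0), y - y.mean())
        beta = lasso_fit(X, y, alpha)
        ref = brute_force_lasso(X, y, alpha, x0=beta)
        Xc, yc = X - X.mean(0), y - y.mean()
        f_cd = penalized_objective(Xc, yc, beta, alpha)
        f_ref = penalized_objective(Xc, yc, ref, alpha)
        assert f_cd <= f_ref + 1e-6
        # and no random perturbation does better
        rng2 = np.random.default_rng(seed)
        for scale in (1e-3, 1e-2, 1e-1):
            pert = beta[None, :] + rng2.standard_normal((500, p)) * scale
            objs = [penalized_objective(Xc, yc, b2, alpha) for b2 in pert]
            assert f_cd <= min(objs) + 1e-12

    def test_matches_sklearn_lasso_path(self):
        # independent implementation cross-check on a shared penalty grid
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(7)
        n, p = 300, 8
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0)
        y = X @ rng.normal(scale=0.3, size=p) + rng.standard_normal(n)
        y -= y.mean()
        alphas = np.geomspace(lambda_max(X, y), 0.01, 20)
        _, coefs, _ = sklearn.lasso_path(X, y, alphas=alphas, tol=1e-12)
        B, ok = cd_path(X.T @ X / n, X.T @ y / n, alphas, 1e-10, 100_000)
        assert ok
        np.testing.assert_allclose(B, coefs.T, atol=1e-6)

    def test_monotone_sparsity_along_path(self):
        rng = np.random.default_rng(8)
        n, p = 200, 10
        X = rng.standard_normal((n, p))
        y = X @ rng.normal(size=p) * 0.2 + rng.standard_normal(n)
        Xc, yc = X - X.mean(0), y - y.mean()
        alphas = np.geomspace(lambda_max(Xc, yc), 1e-4, 60)
        B, ok = cd_path(Xc.T @ Xc / n, Xc.T @ yc / n, alphas, 1e-9, 100_000)
        assert ok
        # support can only grow approximately; allow the occasional drop of
        # a coefficient but require the count at a larger penalty to never
        # exceed the count at the smallest penalty
        counts = (np.abs(B) > 0).sum(axis=1)
        assert counts[0] == 0  # exactly zero at lambda_max
        assert np.all(np.diff(counts) >= 0)  # support grows as the penalty shrinks


class TestFitNodeLasso:
    def test_selected_lambda_on_grid_and_coefficients_sparse(self, medium_panel, fast_config):
        data, _ = medium_panel
        X = data.wave_matrix("w1")
        y = data.wave_matrix("w2")[:, 9]
        coef, lam = fit_node_lasso(X, y, fast_config, subject_ids=data.subjects)
        assert lam > 0
        assert np.count_nonzero(coef) < 13

    def test_zero_variance_outcome_raises(self, medium_panel, fast_config):
        data, _ = medium_panel
        X = data.wave_matrix("w1")
        with pytest.raises(EstimationError, match="zero-variance"):
            fit_node_lasso(X, np.ones(len(X)), fast_config)


class TestEstimateCLPN:
    def test_reproducible_given_cv_seed(self, medium_panel, fast_config):
        data, _ = medium_panel
        a = estimate_clpn(data, ("w1", "w2"), fast_config)
        b = estimate_clpn(data, ("w1", "w2"), fast_config)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.lambdas, b.lambdas)

    def test_subject_order_invariance(self, medium_panel, fast_config):
        data, _ = medium_panel
        base = estimate_clpn(data, ("w1", "w2"), fast_config)
        perm = np.random.default_rng(0).permutation(data.n_subjects)
        permuted = estimate_clpn(data.subset(perm), ("w1", "w2"), fast_config)
        np.testing.assert_allclose(base.W, permuted.W, atol=1e-12)

    def test_scale_equivariance_under_standardization(self, medium_panel, fast_config):
        data, _ = medium_panel
        scaled = data.copy()
        scaled.responses = scaled.responses.copy()
        # blow up one item by 10x on both waves (bypass Likert validation)
        scaled.responses[:, :, 4] *= 10
        scaled.schema = list(scaled.schema)
        base = estimate_clpn(data, ("w1", "w2"), fast_config)
        other = estimate_clpn(scaled, ("w1", "w2"), fast_config)
        np.testing.assert_allclose(base.W, other.W, atol=1e-10)

    def test_zero_variance_item_error_names_item(self, medium_panel, fast_config):
        data, _ = medium_panel
        broken = data.copy()
        broken.responses = broken.responses.copy()
        broken.responses[:, 1, 2] = 1.0
        with pytest.raises(EstimationError, match="ghq_useful"):
            estimate_clpn(broken, ("w1", "w2"), fast_config)

    def test_matches_fit_node_lasso_per_row(self, medium_panel, fast_config):
        data, _ = medium_panel
        net = estimate_clpn(data, ("w1", "w2"), fast_config)
        X = data.wave_matrix("w1")
        y = data.wave_matrix("w2")[:, 6]
        coef, lam = fit_node_lasso(
            X, y, fast_config, subject_ids=data.subjects, node_id="ghq_enjoy"
        )
        np.testing.assert_allclose(net.W[6], coef, atol=1e-10)
        assert net.lambdas[6] == pytest.approx(lam)


class TestEdgeCountAndThreshold:
    def _net(self, W):
        p = W.shape[0]
        return CLPNetwork(
            nodes=[f"n{i}" for i in range(p)], W=W, lambdas=np.zeros(p),
            wave_pair=("w1", "w2"), n_used=100,
        )

    def test_zero_and_identity_matrices(self):
        assert count_nonzero_edges(self._net(np.zeros((5, 5)))) == 0
        assert count_nonzero_edges(self._net(np.eye(5))) == 0
        assert count_nonzero_edges(self._net(np.eye(5)), include_autoregressive=True) == 5

    def test_random_sparse_support_matches_brute_force(self):
        rng = np.random.default_rng(9)
        W = rng.standard_normal((13, 13)) * (rng.random((13, 13)) < 0.2)
        net = self._net(W)
        expected_off = sum(
            1 for i in range(13) for j in range(13) if i != j and W[i, j] != 0
        )
        expected_all = sum(1 for i in range(13) for j in range(13) if W[i, j] != 0)
        assert count_nonzero_edges(net) == expected_off
        assert count_nonzero_edges(net, include_autoregressive=True) == expected_all

    def test_threshold_boundary_is_strict(self):
        W = np.zeros((3, 3))
        W[0, 1] = 0.049
        W[1, 2] = 0.050
        out = apply_display_threshold(self._net(W), 0.05)
        assert out.W[0, 1] == 0.0
        assert out.W[1, 2] == 0.050

    def test_threshold_zero_is_identity_and_idempotent(self):
        rng = np.random.default_rng(10)
        W = rng.standard_normal((4, 4)) * 0.1
        net = self._net(W)
        np.testing.assert_array_equal(apply_display_threshold(net, 0.0).W, W)
        once = apply_display_threshold(net, 0.05)
        twice = apply_display_threshold(once, 0.05)
        np.testing.assert_array_equal(once.W, twice.W)

    def test_original_network_untouched(self):
        W = np.full((3, 3), 0.01)
        net = self._net(W)
        apply_display_threshold(net, 0.05)
        np.testing.assert_array_equal(net.W, W)
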