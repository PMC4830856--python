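"""Graphical lasso, EBIC and partial-correlation conversion."""

import numpy as np
import pytest

from qolnet import (
    CorrelationMatrix,
    EstimationError,
    ebic,
    glasso_fit,
    lambda_path,
    precision_to_pcor,
    select_network,
)
from qolnet.ggm import LambdaPath


def glasso_objective(theta, r, lam):
    """Penalised log-likelihood (off-diagonal penalty only)."""
    sign, logdet = np.linalg.slogdet(theta)
    assert sign > 0
    pen = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
    return logdet - np.trace(r @ theta) - lam * pen


def _cm(values, n=500):
    return CorrelationMatrix(values=np.asarray(values, float), n=n)


class TestLambdaPath:
    def test_endpoints(self):
        r = _cm([[1.0, 0.8], [0.8, 1.0]])
        path = lambda_path(r, m=2, ratio=0.01)
        np.testing.assert_allclose(path.lambdas, [0.8, 0.008])

    def test_default_length_and_monotonicity(self):
        r = _cm([[1.0, 0.5, 0.2], [0.5, 1.0, 0.1], [0.2, 0.1, 1.0]])
        path = lambda_path(r)
        assert path.lambdas.shape == (100,)
        assert path.lambdas[0] == 0.5
        assert np.all(np.diff(path.lambdas) < 0)

    def test_degenerate_all_zero_off_diagonals(self):
        path = lambda_path(_cm(np.eye(3)))
        assert path.lambdas.shape == (1,)


class TestGlassoFit:
    def test_above_lambda_max_gives_diagonal_inverse(self, random_correlation):
        rng = np.random.default_rng(1)
        r = random_correlation(5, rng)
        lam_max = np.abs(r - np.eye(5)).max()
        theta = glasso_fit(_cm(r), lam_max).values
        np.testing.assert_allclose(theta, np.eye(5), atol=1e-8)

    def test_zero_penalty_recovers_inverse(self, random_correlation):
        rng = np.random.default_rng(2)
        r = random_correlation(4, rng)
        theta = glasso_fit(_cm(r), 0.0).values
        np.testing.assert_allclose(theta, np.linalg.inv(r), atol=1e-5)

    def test_agrees_with_sklearn(self, random_correlation):
        """Independent implementation cross-check on random instances."""
        from sklearn.covariance import graphical_lasso

        rng = np.random.default_rng(3)
        for _ in range(10):
            p = int(rng.integers(3, 7))
            r = random_correlation(p, rng)
            lam = float(rng.uniform(0.02, 0.3))
            mine = glasso_fit(_cm(r), lam).values
            _, ref = graphical_lasso(r, alpha=lam, tol=1e-10, max_iter=500)
            np.testing.assert_allclose(mine, ref, atol=5e-4)

    def test_objective_not_worse_than_sklearn(self, random_correlation):
        from sklearn.covariance import graphical_lasso

        rng = np.random.default_rng(4)
        r = random_correlation(5, rng)
        mine = glasso_fit(_cm(r), 0.1).values
        _, ref = graphical_lasso(r, alpha=0.1, tol=1e-10, max_iter=500)
        assert glasso_objective(mine, r, 0.1) >= glasso_objective(ref, r, 0.1) - 1e-7


class TestEbic:
    def test_identity_closed_form(self):
        # l = (100/2)(0 - 3) = -150, E = 0 -> EBIC = 300
        value = ebic(_cm(np.eye(3)), np.eye(3), n=100, gamma=0.5)
        np.testing.assert_allclose(value, 300.0, atol=1e-10)

    def test_gamma_zero_reduces_to_bic(self, random_correlation):
        rng = np.random.default_rng(5)
        for _ in range(10):
            r = random_correlation(4, rng)
            theta = glasso_fit(_cm(r), 0.15).values
            n = int(rng.integers(50, 500))
            n_edges = int(np.count_nonzero(np.triu(theta, 1)))
            sign, logdet = np.linalg.slogdet(theta)
            ll = 0.5 * n * (logdet - np.trace(r @ theta))
            bic = -2 * ll + n_edges * np.log(n)
            np.testing.assert_allclose(ebic(_cm(r), theta, n, 0.0), bic, atol=1e-10)

    def test_formula_oracle(self):
        """Fixed Theta with two edges against an independent re-computation."""
        theta = np.array(
            [[1.2, 0.3, 0.0], [0.3, 1.1, -0.2], [0.0, -0.2, 1.3]]
        )
        r = np.array([[1.0, -0.25, 0.1], [-0.25, 1.0, 0.15], [0.1, 0.15, 1.0]])
        n, gamma = 100, 0.5
        sign, logdet = np.linalg.slogdet(theta)
        ll = 0.5 * n * (logdet - np.trace(r @ theta))
        expected = -2 * ll + 2 * np.log(n) + 4 * 2 * gamma * np.log(3)
        np.testing.assert_allclose(ebic(_cm(r), theta, n, gamma), expected, atol=1e-10)

    def test_non_pd_theta_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(EstimationError):
            ebic(_cm(np.eye(2)), bad, 100, 0.5)


class TestPrecisionToPcor:
    def test_diagonal_theta_gives_empty_network(self):
        w = precision_to_pcor(np.diag([2.0, 3.0, 0.5]))
        np.testing.assert_array_equal(w, np.zeros((3, 3)))

    def test_equicorrelation_closed_form(self):
        """r_12 = r_13 = r_23 = 0.5 gives partial correlations of exactly 1/3."""
        r = np.full((3, 3), 0.5)
        np.fill_diagonal(r, 1.0)
        w = precision_to_pcor(np.linalg.inv(r))
        np.testing.assert_allclose(w[0, 1], 1.0 / 3.0, atol=1e-12)

    def test_symmetric_zero_diagonal(self, random_correlation):
        rng = np.random.default_rng(6)
        r = random_correlation(5, rng)
        w = precision_to_pcor(np.linalg.inv(r))
        np.testing.assert_allclose(w, w.T)
        np.testing.assert_array_equal(np.diag(w), 0.0)


class TestSelectNetwork:
    def test_independent_data_selects_empty_graph(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(1000, 5))
        r = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(r, 1.0)
        net = select_network(_cm(r, n=1000), gamma=0.5)
        assert net.edge_count == 0

    def test_contract_edge_bound_and_lambda_in_path(self, random_correlation):
        rng = np.random.default_rng(9)
        r = random_correlation(6, rng)
        net = select_network(_cm(r, n=300))
        assert net.edge_count <= 6 * 5 // 2
        assert net.lam in net.path.lambdas
        assert np.all(np.abs(net.weights) < 1)

    def test_permutation_equivariance(self, random_correlation):
        """Relabelling nodes permutes the selected weights identically."""
        rng = np.random.default_rng(10)
        r = random_correlation(6, rng)
        perm = rng.permutation(6)
        net = select_network(_cm(r, n=400))
        net_p = select_network(_cm(r[np.ix_(perm, perm)], n=400))
        np.testing.assert_allclose(
            net_p.weights, net.weights[np.ix_(perm, perm)], atol=1e-8
        )

    def test_custom_path_and_metadata(self, random_correlation):
        rng = np.random.default_rng(11)
        r = random_correlation(4, rng)
        path = LambdaPath(lambdas=np.array([0.5, 0.2, 0.05]))
        net = select_network(_cm(r, n=200), path=path, labels=list("abcd"))
        meta = net.metadata()
        assert meta["n"] == 200 and meta["p"] == 4
        assert net.labels == list("abcd")
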