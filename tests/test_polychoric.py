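"""Polychoric estimation against closed forms and a scipy likelihood oracle."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from qolnet import (
    DegenerateItemError,
    ItemSpec,
    OrdinalDataset,
    estimate_thresholds,
    nearest_pd,
    polychoric_matrix,
    polychoric_pair,
)
from qolnet.synthetic import sample_ordinal, thresholds_for


def oracle_loglik(table, tau1, tau2, rho):
    """Independent likelihood evaluation via scipy's bivariate-normal CDF."""
    t1 = np.concatenate([[-np.inf], tau1, [np.inf]])
    t2 = np.concatenate([[-np.inf], tau2, [np.inf]])
    dist = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])

    def cdf(x, y):
        if x == -np.inf or y == -np.inf:
            return 0.0
        from scipy.stats import norm

        if x == np.inf and y == np.inf:
            return 1.0
        if x == np.inf:
            return norm.cdf(y)
        if y == np.inf:
            return norm.cdf(x)
        return dist.cdf([x, y])

    ll = 0.0
    for a in range(table.shape[0]):
        for b in range(table.shape[1]):
            if table[a, b] == 0:
                continue
            pi = (
                cdf(t1[a + 1], t2[b + 1])
                - cdf(t1[a], t2[b + 1])
                - cdf(t1[a + 1], t2[b])
                + cdf(t1[a], t2[b])
            )
            ll += table[a, b] * np.log(max(pi, 1e-12))
    return ll


def grid_oracle(table, tau1, tau2, grid):
    lls = [oracle_loglik(table, tau1, tau2, r) for r in grid]
    return grid[int(np.argmax(lls))]


class TestThresholds:
    def test_even_split_gives_zero(self):
        np.testing.assert_allclose(estimate_thresholds(np.array([50, 50])), [0.0])

    def test_quartiles(self):
        tau = estimate_thresholds(np.array([25, 25, 25, 25]))
        np.testing.assert_allclose(tau, [-0.6744898, 0.0, 0.6744898], atol=1e-6)

    def test_degenerate_item_rejected(self):
        with pytest.raises(DegenerateItemError):
            estimate_thresholds(np.array([100, 0]))

    def test_empty_categories_collapsed(self, caplog):
        with caplog.at_level("WARNING"):
            tau = estimate_thresholds(np.array([0, 30, 70, 0]))
        assert tau.shape == (1,)
        assert "collapsing" in caplog.text


class TestPolychoricPair:
    def test_independent_table_estimates_zero(self):
        table = np.array([[25.0, 25.0], [25.0, 25.0]])
        assert abs(polychoric_pair(table, np.array([0.0]), np.array([0.0]))) < 1e-6

    def test_perfect_concordance_clamps(self):
        table = np.array([[50.0, 0.0], [0.0, 50.0]])
        assert polychoric_pair(table, np.array([0.0]), np.array([0.0])) == 0.999

    def test_tetrachoric_antisymmetry(self):
        """Swapping off-diagonal cells of a symmetric 2x2 flips the sign."""
        zero = np.array([0.0])
        r1 = polychoric_pair(np.array([[40.0, 10.0], [10.0, 40.0]]), zero, zero)
        r2 = polychoric_pair(np.array([[10.0, 40.0], [40.0, 10.0]]), zero, zero)
        assert r1 > 0.3
        np.testing.assert_allclose(r1, -r2, atol=1e-6)

    def test_matches_grid_search_oracle(self):
        """ML estimate within grid spacing of exhaustive likelihood search."""
        rng = np.random.default_rng(7)
        rho_true = 0.5
        cov = [[1, rho_true], [rho_true, 1]]
        z = rng.multivariate_normal([0, 0], cov, size=10_000)
        x = (z[:, 0] > 0).astype(int)
        y = np.searchsorted([-0.5, 0.5], z[:, 1])
        table = np.zeros((2, 3))
        np.add.at(table, (x, y), 1)
        tau1 = estimate_thresholds(table.sum(axis=1))
        tau2 = estimate_thresholds(table.sum(axis=0))
        rho_hat = polychoric_pair(table, tau1, tau2)
        coarse = np.arange(-0.95, 0.96, 0.05)
        near = grid_oracle(table, tau1, tau2, coarse)
        fine = np.arange(near - 0.05, near + 0.0501, 0.001)
        rho_grid = grid_oracle(table, tau1, tau2, fine)
        assert abs(rho_hat - rho_true) <= 0.03
        assert abs(rho_hat - rho_grid) <= 0.0011

    def test_sign_equivariance(self):
        """Reversing one item's category order flips the correlation sign."""
        rng = np.random.default_rng(3)
        cov = [[1, 0.6], [0.6, 1]]
        z = rng.multivariate_normal([0, 0], cov, size=3000)
        x = np.searchsorted([-0.6, 0.4], z[:, 0])
        y = np.searchsorted([0.0], z[:, 1])
        table = np.zeros((3, 2))
        np.add.at(table, (x, y), 1)
        tau1 = estimate_thresholds(table.sum(axis=1))
        tau2 = estimate_thresholds(table.sum(axis=0))
        r_fwd = polychoric_pair(table, tau1, tau2)
        flipped = table[::-1].copy()
        tau1_f = estimate_thresholds(flipped.sum(axis=1))
        r_rev = polychoric_pair(flipped, tau1_f, tau2)
        np.testing.assert_allclose(r_fwd, -r_rev, atol=5e-3)


class TestPolychoricMatrix:
    def test_identical_items_clamp(self):
        values = np.tile(np.array([0, 1, 2, 1, 0, 2])[:, None], (1, 2))
        data = OrdinalDataset(values, [ItemSpec("a", 3), ItemSpec("b", 3)])
        r = polychoric_matrix(data, repair=False)
        assert r.values[0, 1] == 0.999

    def test_independent_items_near_zero(self):
        theta = np.eye(3)
        taus = thresholds_for(np.array([3, 4, 5]))
        data = sample_ordinal(theta, taus, 2000, seed=21)
        r = polychoric_matrix(data)
        off = r.values[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_contract_symmetric_unit_diag_pd(self):
        theta, _ = _chain_theta(5)
        data = sample_ordinal(theta, thresholds_for(np.full(5, 4)), 400, seed=2)
        r = polychoric_matrix(data)
        np.testing.assert_allclose(r.values, r.values.T)
        np.testing.assert_allclose(np.diag(r.values), 1.0)
        assert np.linalg.eigvalsh(r.values)[0] > 0

    def test_method_tag(self):
        data = sample_ordinal(np.eye(2), thresholds_for(np.array([2, 2])), 100, seed=0)
        assert polychoric_matrix(data).method == "polychoric"


def _chain_theta(p):
    from qolnet.synthetic import SyntheticSpec, make_precision

    return make_precision(SyntheticSpec(p=p, structure="chain", seed=5))


class TestNearestPd:
    def test_identity_is_fixed_point(self):
        out = nearest_pd(np.eye(4))
        np.testing.assert_array_equal(out.values, np.eye(4))

    def test_indefinite_matrix_repaired(self):
        r = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        assert np.linalg.eigvalsh(r)[0] < 0  # needs repair by construction
        out = nearest_pd(r)
        assert np.linalg.eigvalsh(out.values)[0] >= 1e-6 - 1e-12
        np.testing.assert_allclose(np.diag(out.values), 1.0)

    def test_minimum_eigenvalue_contract(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(-1, 1, size=(6, 6))
        r = (a + a.T) / 2
        np.fill_diagonal(r, 1.0)
        out = nearest_pd(r, eps=1e-4)
        assert np.linalg.eigvalsh(out.values)[0] >= 1e-4 - 1e-10
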