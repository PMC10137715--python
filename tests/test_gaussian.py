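"""Exponential-family structure, divergences and the affine action."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import multivariate_normal

import fisherrao as fr
from fisherrao.gaussian import from_cholesky, to_cholesky

from conftest import random_gaussian


class TestParameterizations:
    def test_natural_params_standard_normal(self):
        th = fr.to_natural(fr.Gaussian([0.0], [[1.0]]))
        assert th.theta_v[0] == pytest.approx(0.0)
        assert th.theta_M[0, 0] == pytest.approx(0.5)

    def test_expectation_params_shifted(self):
        # N(1, 2): eta = (mu, -Sigma - mu mu^T) = (1, -3)
        eta = fr.to_expectation(fr.Gaussian([1.0], [[2.0]]))
        assert eta.eta_v[0] == pytest.approx(1.0)
        assert eta.eta_H[0, 0] == pytest.approx(-3.0)

    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_round_trips(self, rng, d):
        g = random_gaussian(rng, d)
        g2 = fr.from_natural(fr.to_natural(g))
        g3 = fr.from_expectation(fr.to_expectation(g2))
        assert g3.allclose(g, atol=1e-10)
        mu, L = to_cholesky(g)
        assert from_cholesky(mu, L).allclose(g, atol=1e-10)

    def test_non_spd_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive-definite"):
            fr.Gaussian([0.0, 0.0], [[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            fr.NaturalParam([0.0], [[-1.0]])
        with pytest.raises(ValueError):
            fr.ExpectationParam([2.0], [[-1.0]])  # -H - vv^T = -3 < 0


class TestPotentials:
    def test_log_partition_matches_quadrature(self):
        # F(theta) = log int exp(theta_v x - theta_M x^2) dx for d=1
        g = fr.Gaussian([0.7], [[1.3]])
        th = fr.to_natural(g)
        tv, tM = th.theta_v[0], th.theta_M[0, 0]
        val, _ = quad(lambda x: np.exp(tv * x - tM * x * x), -30, 30)
        assert fr.log_partition(th) == pytest.approx(np.log(val), abs=1e-9)

    def test_log_partition_additive_over_independent_coords(self):
        f1 = fr.log_partition(fr.to_natural(fr.Gaussian([0.0], [[1.0]])))
        f2 = fr.log_partition(fr.to_natural(fr.Gaussian([0.0, 0.0], np.eye(2))))
        assert f2 == pytest.approx(2 * f1)

    def test_gradient_of_log_partition_is_expectation_param(self, rng):
        g = random_gaussian(rng, 2)
        th = fr.to_natural(g)
        eta = fr.to_expectation(g)
        eps = 1e-6
        # vector part
        for i in range(2):
            dv = np.zeros(2)
            dv[i] = eps
            up = fr.log_partition(fr.NaturalParam(th.theta_v + dv, th.theta_M))
            dn = fr.log_partition(fr.NaturalParam(th.theta_v - dv, th.theta_M))
            assert (up - dn) / (2 * eps) == pytest.approx(eta.eta_v[i], abs=1e-5)
        # matrix part (symmetric perturbations)
        for i in range(2):
            for j in range(i, 2):
                dM = np.zeros((2, 2))
                dM[i, j] = dM[j, i] = eps
                up = fr.log_partition(fr.NaturalParam(th.theta_v, th.theta_M + dM))
                dn = fr.log_partition(fr.NaturalParam(th.theta_v, th.theta_M - dM))
                grad = (up - dn) / (2 * eps)
                expect = eta.eta_H[i, j] * (2.0 if i != j else 1.0)
                assert grad == pytest.approx(expect, abs=1e-5)

    def test_dual_potential_is_negentropy(self, rng):
        g = random_gaussian(rng, 3)
        eta = fr.to_expectation(g)
        ent = multivariate_normal(g.mean, g.cov).entropy()
        assert fr.dual_potential(eta) == pytest.approx(-ent, abs=1e-10)

    def test_legendre_identity(self, rng):
        g = random_gaussian(rng, 2)
        th, eta = fr.to_natural(g), fr.to_expectation(g)
        inner = th.theta_v @ eta.eta_v + np.sum(th.theta_M * eta.eta_H)
        assert fr.log_partition(th) + fr.dual_potential(eta) == pytest.approx(
            inner, abs=1e-10
        )

    def test_fenchel_young_gap_nonnegative(self, rng):
        g1, g2 = random_gaussian(rng, 2), random_gaussian(rng, 2)
        gap = fr.fenchel_young(fr.to_natural(g1), fr.to_expectation(g2))
        assert gap >= -1e-12


class TestDivergences:
    def test_kl_zero_iff_equal(self, rng):
        g = random_gaussian(rng, 3)
        assert fr.kl_divergence(g, g) == pytest.approx(0.0, abs=1e-12)
        h = random_gaussian(rng, 3)
        assert fr.kl_divergence(g, h) > 0

    def test_kl_unit_mean_shift(self):
        g1, g2 = fr.Gaussian([0.0], [[1.0]]), fr.Gaussian([1.0], [[1.0]])
        assert fr.kl_divergence(g1, g2) == pytest.approx(0.5)

    def test_kl_matches_monte_carlo(self, rng):
        g1, g2 = random_gaussian(rng, 2), random_gaussian(rng, 2)
        x = rng.multivariate_normal(g1.mean, g1.cov, size=200_000)
        lp = multivariate_normal(g1.mean, g1.cov).logpdf(x)
        lq = multivariate_normal(g2.mean, g2.cov).logpdf(x)
        diffs = lp - lq
        mc, se = diffs.mean(), diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(fr.kl_divergence(g1, g2) - mc) < 3 * se

    def test_jeffreys_symmetric_and_sum_of_kls(self, rng):
        g1, g2 = random_gaussian(rng, 3), random_gaussian(rng, 3)
        dj = fr.jeffreys(g1, g2)
        assert dj == pytest.approx(fr.jeffreys(g2, g1), rel=1e-12)
        assert dj == pytest.approx(
            fr.kl_divergence(g1, g2) + fr.kl_divergence(g2, g1), rel=1e-10
        )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            fr.kl_divergence(
                fr.Gaussian([0.0], [[1.0]]), fr.Gaussian([0.0, 0.0], np.eye(2))
            )

    def test_bregman_is_reverse_kl(self, rng):
        g1, g2 = random_gaussian(rng, 2), random_gaussian(rng, 2)
        b = fr.bregman_fy(fr.to_natural(g1), fr.to_natural(g2))
        assert b == pytest.approx(fr.kl_divergence(g2, g1), abs=1e-9)
        assert fr.bregman_fy(fr.to_natural(g1), fr.to_natural(g1)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_fenchel_young_equals_bregman_at_dual_point(self, rng):
        g1, g2 = random_gaussian(rng, 2), random_gaussian(rng, 2)
        y = fr.fenchel_young(fr.to_natural(g1), fr.to_expectation(g2))
        b = fr.bregman_fy(fr.to_natural(g1), fr.to_natural(g2))
        assert y == pytest.approx(b, abs=1e-9)

    def test_symmetrized_bregman_is_parameter_inner_product(self, rng):
        # B(th1:th2) + B(th2:th1) = <th2 - th1, eta2 - eta1>
        g1, g2 = random_gaussian(rng, 3), random_gaussian(rng, 3)
        th1, th2 = fr.to_natural(g1), fr.to_natural(g2)
        e1, e2 = fr.to_expectation(g1), fr.to_expectation(g2)
        lhs = fr.bregman_fy(th1, th2) + fr.bregman_fy(th2, th1)
        rhs = (th2.theta_v - th1.theta_v) @ (e2.eta_v - e1.eta_v) + np.sum(
            (th2.theta_M - th1.theta_M) * (e2.eta_H - e1.eta_H)
        )
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestMahalanobis:
    def test_worked_example(self):
        S = np.array([[1.1, 0.9], [0.9, 1.1]])
        assert fr.mahalanobis([-1, 0], [6, 3], S) == pytest.approx(8.06226, abs=1e-4)

    def test_identity_cov_is_euclidean(self, rng):
        a, b = rng.standard_normal(3), rng.standard_normal(3)
        assert fr.mahalanobis(a, b, np.eye(3)) == pytest.approx(
            np.linalg.norm(a - b)
        )

    def test_whitening_identity(self, rng):
        from conftest import random_spd

        S = random_spd(rng, 3)
        a, b = rng.standard_normal(3), rng.standard_normal(3)
        L = np.linalg.cholesky(S)
        assert fr.mahalanobis(a, b, S) == pytest.approx(
            np.linalg.norm(np.linalg.solve(L, b - a)), rel=1e-10
        )

    def test_singular_sigma_rejected(self):
        with pytest.raises(ValueError):
            fr.mahalanobis([0, 0], [1, 1], np.zeros((2, 2)))


class TestAffineAction:
    def test_identity_map(self, rng):
        g = random_gaussian(rng, 2)
        ident = fr.AffineMap(np.eye(2), np.zeros(2))
        assert fr.affine_act(ident, g).allclose(g)

    def test_action_on_standard_normal(self, rng):
        A = rng.standard_normal((2, 2)) + 2 * np.eye(2)
        a = rng.standard_normal(2)
        g = fr.affine_act(fr.AffineMap(A, a), fr.Gaussian(np.zeros(2), np.eye(2)))
        assert np.allclose(g.mean, a)
        assert np.allclose(g.cov, A @ A.T)

    def test_group_law(self, rng):
        g = random_gaussian(rng, 2)
        m1 = fr.AffineMap(rng.standard_normal((2, 2)) + 2 * np.eye(2), rng.standard_normal(2))
        m2 = fr.AffineMap(rng.standard_normal((2, 2)) + 2 * np.eye(2), rng.standard_normal(2))
        lhs = fr.affine_act(m1.compose(m2), g)
        rhs = fr.affine_act(m1, fr.affine_act(m2, g))
        assert lhs.allclose(rhs, atol=1e-10)

    def test_singular_map_rejected(self):
        with pytest.raises(ValueError, match="invertible"):
            fr.AffineMap(np.zeros((2, 2)), np.zeros(2))


class TestFisherLineElement:
    def test_mean_perturbation(self):
        g = fr.Gaussian([0.0], [[1.0]])
        assert fr.fisher_line_element(g, [1e-3], [[0.0]]) == pytest.approx(1e-6)

    def test_cov_perturbation(self):
        g = fr.Gaussian([0.0], [[1.0]])
        assert fr.fisher_line_element(g, [0.0], [[1e-3]]) == pytest.approx(0.5e-6)

    def test_twice_kl_approaches_line_element(self, rng):
        g = random_gaussian(rng, 2)
        dmu = 0.37 * rng.standard_normal(2)
        dS = rng.standard_normal((2, 2))
        dS = 0.23 * (dS + dS.T)
        ds2 = fr.fisher_line_element(g, dmu, dS)
        for eps in (1e-2, 1e-3):
            gp = fr.Gaussian(g.mean + eps * dmu, g.cov + eps * dS)
            ratio = 2 * fr.kl_divergence(g, gp) / (eps**2 * ds2)
            assert ratio == pytest.approx(1.0, abs=0.05 if eps == 1e-2 else 0.005)

    def test_asymmetric_perturbation_rejected(self, rng):
        g = random_gaussian(rng, 2)
        with pytest.raises(ValueError, match="symmetric"):
            fr.fisher_line_element(g, [0, 0], [[0.0, 1.0], [0.0, 0.0]])
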