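"""Model-based estimator tests: exact values, oracles, and Monte-Carlo checks.

The coefficient operations are checked against independent brute-force
solutions: Fu's BLUE against the bordered-system solution of the
equality-constrained quadratic program, and the Futschik minimum-MSE
coefficients against the normal equations of the linear MMSE problem.
"""

from fractions import Fraction

import numpy as np
import pytest
import scipy.linalg as sla
from hypothesis import given, settings
from hypothesis import strategies as st

from thetanet import (
    CoalescentParams,
    FuModel,
    IterationConfig,
    IterativeEstimator,
    SiteFrequencySpectrum,
    WattersonEstimator,
    beta_n,
    fu_blue_coefficients,
    fu_sigma,
    futschik_mmse_coefficients,
    futschik_segregating_coefficient,
    harmonic_sums,
    iterate_batch,
    iterate_estimator,
    simulate_kingman_sfs,
    simulate_unlinked_sfs,
    watterson,
    watterson_variance,
)


def exact_harmonics(n):
    h = sum((Fraction(1, i) for i in range(1, n)), Fraction(0))
    g = sum((Fraction(1, i * i) for i in range(1, n)), Fraction(0))
    return h, g


class TestHarmonics:
    @pytest.mark.parametrize("n,expected", [(2, (1.0, 1.0)), (3, (1.5, 1.25)),
                                            (5, (25 / 12, 205 / 144))])
    def test_small_values(self, n, expected):
        assert harmonic_sums(n) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("n", [2, 7, 40, 100])
    def test_matches_exact_rational_sums(self, n):
        h, g = harmonic_sums(n)
        he, ge = exact_harmonics(n)
        assert h == pytest.approx(float(he), rel=1e-14)
        assert g == pytest.approx(float(ge), rel=1e-14)

    def test_strictly_increasing_in_n(self):
        hs = [harmonic_sums(n) for n in range(2, 30)]
        assert all(b > a for (a, _), (b, _) in zip(hs, hs[1:]))
        assert all(b > a for (_, a), (_, b) in zip(hs, hs[1:]))

    def test_rejects_n_below_two(self):
        with pytest.raises(ValueError):
            harmonic_sums(1)


class TestBetaAndSigma:
    def test_beta_3_of_2(self):
        # 2*3*(h_4 - h_2)/((3-2+1)(3-2)) - 2/(3-2) with h_4=11/6, h_2=1
        assert beta_n(3, 2) == pytest.approx(0.5, abs=1e-14)

    def test_beta_2_of_1_exact_rational(self):
        # 2*2*(h_3 - h_1)/((2-1+1)(2-1)) - 2/(2-1) = 4*(3/2)/2 - 2 = 1
        he = Fraction(3, 2)
        expected = float(Fraction(4) * he / 2 - 2)
        assert beta_n(2, 1) == pytest.approx(expected, abs=1e-14)

    def test_beta_index_range(self):
        with pytest.raises(ValueError):
            beta_n(5, 5)
        with pytest.raises(ValueError):
            beta_n(5, 0)

    def test_sigma_n2_is_one(self):
        # Var(S_1) at n=2 is theta + theta^2 (Poisson-Exponential mixture),
        # matching theta*alpha_1 + theta^2*sigma_11 with sigma_11 = 1.
        assert fu_sigma(2).sigma == pytest.approx(np.array([[1.0]]))

    @pytest.mark.parametrize("n", [3, 6, 10, 25, 40])
    def test_sigma_symmetric(self, n):
        sigma = fu_sigma(n).sigma
        np.testing.assert_array_equal(sigma, sigma.T)

    @given(n=st.integers(2, 30), theta=st.floats(0.01, 200.0))
    @settings(max_examples=40, deadline=None)
    def test_model_covariance_positive_semidefinite(self, n, theta):
        model = FuModel(n)
        eig = np.linalg.eigvalsh(model.covariance(theta))
        assert eig.min() >= -1e-9 * max(1.0, eig.max())

    def test_sigma_matches_empirical_kingman_covariance(self):
        # theta*D_alpha + theta^2*Sigma must reproduce simulated SFS
        # covariances; this pins the beta_n/sigma_ij reconstruction.
        n, theta, reps = 10, 5.0, 200_000
        ds = simulate_kingman_sfs(
            CoalescentParams(n, theta), reps, rng=np.random.default_rng(42)
        )
        x = ds.sfs - ds.sfs.mean(axis=0)
        emp = (x.T @ x) / reps
        prods = np.einsum("ri,rj->rij", x, x)
        se = prods.std(axis=0) / np.sqrt(reps)
        expected = FuModel(n).covariance(theta)
        assert np.all(np.abs(emp - expected) <= 4 * se)


class TestWatterson:
    def test_n2_single_count(self):
        assert watterson(SiteFrequencySpectrum(np.array([5]), 2)) == 5.0

    def test_n3_direct_formula(self):
        assert watterson(SiteFrequencySpectrum(np.array([3, 1]), 3)) == pytest.approx(8 / 3)

    def test_zero_sfs(self):
        assert watterson(np.zeros(9)) == 0.0

    def test_matrix_input_vectorizes(self):
        mat = np.array([[3, 1], [0, 0], [1, 1]])
        np.testing.assert_allclose(watterson(mat), [8 / 3, 0.0, 4 / 3])

    @pytest.mark.parametrize("theta,n,regime,expected", [
        (1.0, 2, "linked", 2.0),
        (1.0, 2, "unlinked", 1.0),
        (0.0, 17, "linked", 0.0),
        (0.0, 17, "unlinked", 0.0),
    ])
    def test_variance_closed_forms(self, theta, n, regime, expected):
        assert watterson_variance(theta, n, regime) == pytest.approx(expected)

    def test_variance_unknown_regime(self):
        with pytest.raises(ValueError):
            watterson_variance(1.0, 5, "semi-linked")

    def test_unbiased_on_kingman_and_unlinked(self):
        n, reps = 40, 20_000
        for theta in (5.0, 40.0):
            for sim in (simulate_kingman_sfs, simulate_unlinked_sfs):
                ds = sim(CoalescentParams(n, theta), reps,
                         rng=np.random.default_rng(7))
                w = watterson(ds.sfs)
                se = w.std(ddof=1) / np.sqrt(reps)
                assert abs(w.mean() - theta) < 3 * se


class TestCoefficientOracles:
    """Dual-route check: implementation vs brute-force solvers."""

    @staticmethod
    def blue_oracle(model, theta):
        # equality-constrained QP: min a' M a  s.t.  a'alpha = 1, via the
        # bordered KKT system.
        if theta > 0:
            m = theta * np.diag(model.alpha) + theta**2 * model.sigma
        else:
            m = np.diag(model.alpha)
        k = model.n - 1
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = 2 * m
        kkt[:k, k] = model.alpha
        kkt[k, :k] = model.alpha
        rhs = np.zeros(k + 1)
        rhs[k] = 1.0
        return sla.solve(kkt, rhs)[:k]

    @staticmethod
    def mmse_oracle(model, theta):
        # normal equations: a = (Cov + mu mu')^{-1} mu theta, mu = theta*alpha
        mu = theta * model.alpha
        cov = model.covariance(theta)
        return sla.solve(cov + np.outer(mu, mu), mu * theta, assume_a="pos")

    @pytest.mark.parametrize("n", range(2, 13))
    @pytest.mark.parametrize("theta", [0.1, 1.0, 10.0, 100.0])
    def test_blue_matches_constrained_qp(self, n, theta):
        model = FuModel(n)
        a = fu_blue_coefficients(model, theta).coeffs
        np.testing.assert_allclose(a, self.blue_oracle(model, theta), atol=1e-8)

    @pytest.mark.parametrize("n", range(2, 13))
    @pytest.mark.parametrize("theta", [0.1, 1.0, 10.0, 100.0])
    def test_mmse_matches_normal_equations(self, n, theta):
        model = FuModel(n)
        a = futschik_mmse_coefficients(model, theta).coeffs
        np.testing.assert_allclose(a, self.mmse_oracle(model, theta), atol=1e-8)

    def test_blue_n2_is_unit_coefficient(self):
        model = FuModel(2)
        for theta in (0.0, 1.0, 50.0):
            assert fu_blue_coefficients(model, theta).coeffs == pytest.approx([1.0])

    def test_blue_at_zero_theta_is_watterson(self, fu_model_10):
        a = fu_blue_coefficients(fu_model_10, 0.0).coeffs
        h, _ = harmonic_sums(10)
        np.testing.assert_allclose(a, np.full(9, 1 / h), atol=1e-12)

    @pytest.mark.parametrize("theta,expected", [(1.0, 1 / 3), (1e6, 0.5)])
    def test_mmse_n2_closed_form(self, theta, expected):
        # minimize E[(a S_1 - theta)^2] with E S_1 = theta, Var S_1 =
        # theta + theta^2  =>  a* = theta / (1 + 2 theta)
        a = futschik_mmse_coefficients(FuModel(2), theta).coeffs
        assert a == pytest.approx([theta / (1 + 2 * theta)], rel=1e-6)

    @given(theta=st.floats(1e-3, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_blue_unbiasedness_constraint(self, theta):
        model = FuModel(12)
        a = fu_blue_coefficients(model, theta).coeffs
        assert abs(a @ model.alpha - 1.0) < 1e-10

    def test_blue_perturbations_only_increase_model_variance(self, fu_model_10):
        theta = 5.0
        model = fu_model_10
        cov = model.covariance(theta)
        a = fu_blue_coefficients(model, theta).coeffs
        base = a @ cov @ a
        rng = np.random.default_rng(3)
        for _ in range(100):
            delta = rng.normal(size=9)
            delta -= (delta @ model.alpha) / (model.alpha @ model.alpha) * model.alpha
            a_pert = a + 1e-3 * delta
            assert a_pert @ cov @ a_pert >= base - 1e-12

    def test_segregating_coefficient_values(self):
        m2 = FuModel(2)
        assert futschik_segregating_coefficient(m2, 1.0) == pytest.approx(1 / 3)
        m40 = FuModel(40)
        h, g = m40.h, m40.g
        # shrinks below Watterson for any theta; approaches h/(g+h^2)
        for theta in (0.1, 1.0, 10.0, 1e8):
            assert futschik_segregating_coefficient(m40, theta) < 1 / h
        assert futschik_segregating_coefficient(m40, 1e12) == pytest.approx(
            h / (g + h**2), rel=1e-3
        )

    def test_requires_positive_theta(self):
        with pytest.raises(ValueError):
            futschik_mmse_coefficients(FuModel(5), 0.0)
        with pytest.raises(ValueError):
            futschik_segregating_coefficient(FuModel(5), -1.0)


class TestIteration:
    def test_zero_sfs_is_fixed_point(self):
        for family in ("fu", "futschik", "futschik_segregating"):
            theta, n_iter, converged = iterate_estimator(np.zeros(39), family)
            assert theta == 0.0 and converged

    def test_batch_and_scalar_agree(self, kingman_n40_theta40):
        sfs = kingman_n40_theta40.sfs[:20]
        batch, iters, conv = iterate_batch(sfs, "fu")
        singles = [iterate_estimator(row, "fu") for row in sfs]
        np.testing.assert_allclose(batch, [s[0] for s in singles])
        assert conv.all()

    def test_iterative_fu_near_unbiased(self, kingman_n40_theta40):
        theta_hat, _, conv = iterate_batch(kingman_n40_theta40.sfs, "fu")
        assert conv.all()
        se = theta_hat.std(ddof=1) / np.sqrt(len(theta_hat))
        assert abs(theta_hat.mean() - 40.0) < 3 * se

    def test_convergence_is_fast(self, kingman_n40_theta40):
        _, n_iter, conv = iterate_batch(kingman_n40_theta40.sfs[:500], "fu")
        assert conv.all()
        assert np.median(n_iter) <= 6

    def test_nonconvergence_flagged_at_iteration_cap(self, kingman_n40_theta40):
        _, n_iter, conv = iterate_batch(
            kingman_n40_theta40.sfs[:5], "fu",
            IterationConfig(tol=1e-15, max_iter=2),
        )
        assert not conv.any()
        assert (n_iter == 2).all()

    def test_wrapper_validates_width(self):
        est = IterativeEstimator(10, "fu")
        with pytest.raises(ValueError):
            est(np.zeros((3, 5)))

    def test_watterson_wrapper_matches_function(self, kingman_n40_theta40):
        est = WattersonEstimator(40)
        np.testing.assert_allclose(
            est(kingman_n40_theta40.sfs[:50]), watterson(kingman_n40_theta40.sfs[:50])
        )
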