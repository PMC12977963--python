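"""Legendre basis, logistic curve and SAD(1) covariance oracles."""

import numpy as np
import pytest

from idopnet.basis import (
    LogisticParams,
    SAD1Params,
    logistic_curve,
    lop_antiderivative,
    lop_basis,
    sad1_cov,
    sad1_whiten,
    smooth_series,
)


def rodrigues(x, r):
    """Brute-force Rodrigues-formula evaluation (independent oracle)."""
    import sympy

    t = sympy.symbols("t")
    expr = sympy.diff((t**2 - 1) ** r, t, r) / (2**r * sympy.factorial(r))
    f = sympy.lambdify(t, expr, "numpy")
    return np.asarray(f(np.asarray(x)), dtype=float) * np.ones(len(x))


class TestLOPBasis:
    def test_constant_and_endpoint_values(self):
        basis = lop_basis(np.linspace(2.0, 30.0, 9), order=3)
        assert np.allclose(basis.P[:, 0], 1.0)
        assert basis.scaled_times[0] == -1.0 and basis.scaled_times[-1] == 1.0
        # every Legendre polynomial equals 1 at the right endpoint
        assert np.allclose(basis.P[-1], 1.0)

    @pytest.mark.parametrize("order", [1, 2, 3, 5])
    def test_matches_rodrigues_formula(self, order):
        basis = lop_basis(np.linspace(0.0, 10.0, 11), order=order)
        for r in range(order + 1):
            expected = rodrigues(basis.scaled_times, r)
            assert np.allclose(basis.P[:, r], expected, atol=1e-10)

    def test_columns_orthogonal_under_continuous_inner_product(self):
        basis = lop_basis(np.linspace(-1.0, 1.0, 2001), order=4)
        x = basis.scaled_times
        for i in range(5):
            for j in range(i):
                ip = np.trapezoid(basis.P[:, i] * basis.P[:, j], x)
                assert abs(ip) < 1e-3

    def test_constant_grid_rejected(self):
        with pytest.raises(ValueError):
            lop_basis(np.array([3.0, 3.0, 3.0]), order=2)


class TestAntiderivative:
    def test_constant_integrates_to_interval_length(self):
        basis = lop_antiderivative(lop_basis(np.linspace(0, 28, 15), 2))
        assert np.allclose(basis.Q[0], 0.0)
        assert np.isclose(basis.Q[-1, 0], 2.0)  # integral of 1 over [-1, 1]
        assert np.all(np.diff(basis.Q[:, 0]) >= 0)

    def test_odd_function_integrates_to_zero(self):
        basis = lop_antiderivative(lop_basis(np.linspace(0, 10, 101), 1))
        assert abs(basis.Q[-1, 1]) < 1e-12

    def test_quadratic_matches_analytic_antiderivative(self):
        # int p_2 = (t^3 - t)/2, anchored at the first grid point
        basis = lop_antiderivative(lop_basis(np.linspace(0, 1, 501), 2))
        x = basis.scaled_times
        analytic = (x**3 - x) / 2.0 - (x[0] ** 3 - x[0]) / 2.0
        assert np.allclose(basis.Q[:, 2], analytic, atol=1e-5)


class TestLogistic:
    def test_value_at_zero_and_asymptote(self):
        p = LogisticParams(a=10.0, b=9.0, r=0.7)
        assert np.isclose(logistic_curve(p, np.array([0.0]))[0], 1.0)
        assert np.isclose(logistic_curve(p, np.array([1e4]))[0], 10.0,
                          atol=1e-6 * 10.0)

    def test_closed_form_point(self):
        p = LogisticParams(a=12.0, b=5.0, r=0.4)
        expected = 12.0 / (1.0 + 5.0 * np.exp(-0.4 * 5.0))
        assert np.isclose(logistic_curve(p, np.array([5.0]))[0], expected)

    @pytest.mark.parametrize("a,b,r", [(10, 9, 0.5), (15, 2, 0.3), (8, 80, 0.6)])
    def test_monotone_bounded_and_satisfies_ode(self, a, b, r):
        p = LogisticParams(a=a, b=b, r=r)
        t = np.linspace(0.0, 30.0, 2001)
        y = logistic_curve(p, t)
        assert np.all(np.diff(y) > 0)
        assert np.all(y < a)
        dy = np.gradient(y, t)[1:-1]  # one-sided endpoint stencils excluded
        assert np.allclose(dy, (r * y * (1 - y / a))[1:-1], atol=1e-3 * a)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            LogisticParams(a=-1.0, b=9.0, r=0.5)


class TestSAD1:
    def test_phi_zero_gives_diagonal(self):
        bundle = sad1_cov(SAD1Params(phi=0.0, nu2=2.5), T=5)
        assert np.allclose(bundle.cov, 2.5 * np.eye(5))

    def test_determinant_is_nu2_to_T(self):
        bundle = sad1_cov(SAD1Params(phi=0.5, nu2=1.0), T=3)
        assert np.isclose(np.linalg.det(bundle.cov), 1.0)
        assert np.isclose(bundle.logdet, 0.0)

    @pytest.mark.parametrize("phi,nu2,T", [
        (0.8, 2.0, 6), (0.3, 0.5, 4), (-0.6, 1.7, 9), (0.95, 3.0, 12),
    ])
    def test_closed_forms_match_dense_linear_algebra(self, phi, nu2, T):
        bundle = sad1_cov(SAD1Params(phi=phi, nu2=nu2), T=T)
        dense_inv = np.linalg.inv(bundle.cov)
        assert np.allclose(bundle.inv, dense_inv, rtol=1e-8, atol=1e-10)
        sign, dense_logdet = np.linalg.slogdet(bundle.cov)
        assert sign == 1.0
        assert np.isclose(bundle.logdet, dense_logdet, rtol=1e-8)
        assert np.allclose(bundle.inv @ bundle.cov, np.eye(T), atol=1e-10)

    def test_whitening_reproduces_quadratic_form(self):
        rng = np.random.default_rng(3)
        params = SAD1Params(phi=0.7, nu2=1.3)
        T = 8
        bundle = sad1_cov(params, T)
        r = rng.normal(size=T)
        eps = sad1_whiten(r, params.phi)
        assert np.isclose(eps @ eps / params.nu2, r @ bundle.inv @ r)

    def test_invalid_variance_rejected(self):
        with pytest.raises(ValueError):
            SAD1Params(phi=0.5, nu2=0.0)


class TestSmoothing:
    def test_recovers_smooth_signal_from_noise(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 28, 15)
        clean = 10.0 / (1.0 + 8.0 * np.exp(-0.4 * t))
        noisy = clean + rng.normal(0, 0.5, t.size)
        fitted, s2 = smooth_series(noisy, t, return_noise=True)
        assert np.mean((fitted - clean) ** 2) < np.mean((noisy - clean) ** 2)
        assert 0.05 < s2 < 2.0  # in the neighbourhood of the true 0.25
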