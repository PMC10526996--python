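import numpy as np
import pytest
from scipy.integrate import quad

from dermaflux.domain import SkinBarrier
from dermaflux.robin import (
    robin_coefficients,
    robin_eigensystem,
    robin_eigenvalues,
    robin_profile,
    robin_response,
    robin_response_curve,
    robin_steady_state,
    steady_profile,
)
from dermaflux.series import conc_profile_dirichlet, response_flux

# FD oracle value (Crank-Nicolson, nx=1201, dt_bar=2e-5, alpha_bar=1)
FD_ROBIN1_X05_T01 = 0.26418203186964917
FD_ROBIN1_X05_T02 = 0.4405870949544708


def bisection_root(alpha_bar: float, n: int, iters: int = 200) -> float:
    """Independent bisection oracle for the n-th eigenvalue."""
    f = lambda m: m * np.cos(m) + alpha_bar * np.sin(m)
    lo, hi = (n - 0.5) * np.pi + 1e-12, n * np.pi - 1e-12
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestEigenvalues:
    def test_unit_sensitivity_roots(self):
        mu = robin_eigenvalues(1.0, 2)
        assert mu[0] == pytest.approx(2.02876, abs=1e-5)
        assert mu[1] == pytest.approx(4.91318, abs=1e-5)

    @pytest.mark.parametrize("alpha_bar", [0.2, 1.0, 5.0])
    def test_against_bisection_oracle(self, alpha_bar):
        mu = robin_eigenvalues(alpha_bar, 5)
        for n in range(1, 6):
            assert mu[n - 1] == pytest.approx(bisection_root(alpha_bar, n), abs=1e-12)

    @pytest.mark.parametrize("alpha_bar", [0.05, 0.2, 1.0, 5.0, 40.0])
    def test_interlacing_and_residuals(self, alpha_bar):
        es = robin_eigensystem(alpha_bar, 30)
        n = np.arange(1, 31)
        assert np.all(es.mu > (n - 0.5) * np.pi)
        assert np.all(es.mu < n * np.pi)
        assert np.all(np.diff(es.mu) > 0)
        assert np.max(np.abs(es.residuals())) < 1e-10

    def test_dirichlet_limit(self):
        mu = robin_eigenvalues(1e8, 5)
        np.testing.assert_allclose(mu, np.arange(1, 6) * np.pi, atol=1e-6)

    def test_neumann_limit(self):
        mu = robin_eigenvalues(1e-8, 5)
        np.testing.assert_allclose(mu, (np.arange(1, 6) - 0.5) * np.pi, atol=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            robin_eigenvalues(0.0, 3)
        with pytest.raises(ValueError):
            robin_eigenvalues(1.0, 0)


class TestCoefficients:
    @pytest.mark.parametrize("alpha_bar", [0.2, 1.0, 5.0])
    def test_against_quadrature_projection(self, alpha_bar):
        mu = robin_eigenvalues(alpha_bar, 3)
        b = robin_coefficients(alpha_bar, mu)
        for k in range(3):
            num = quad(lambda x: steady_profile(x, alpha_bar) * np.sin(mu[k] * x),
                       0, 1, epsabs=1e-14)[0]
            den = quad(lambda x: np.sin(mu[k] * x) ** 2, 0, 1, epsabs=1e-14)[0]
            assert b[k] == pytest.approx(-num / den, abs=1e-10)

    def test_eigenfunction_orthogonality(self):
        mu = robin_eigenvalues(1.0, 4)
        for i in range(4):
            for j in range(i + 1, 4):
                inner = quad(lambda x: np.sin(mu[i] * x) * np.sin(mu[j] * x),
                             0, 1, epsabs=1e-14)[0]
                assert abs(inner) < 1e-10

    def test_initial_condition_reconstruction_converges(self):
        # the expanded initial state has a unit jump at the blood boundary,
        # so pointwise convergence away from it is O(1/n_modes)
        x = np.linspace(0.1, 0.9, 161)
        errs = []
        for n_modes in (1000, 2000):
            es = robin_eigensystem(1.0, n_modes)
            recon = steady_profile(x, 1.0) + np.sin(np.outer(x, es.mu)) @ es.b
            errs.append(np.max(np.abs(recon)))
        assert errs[1] < 1.5e-3
        assert errs[1] < 0.6 * errs[0]  # halves when modes double

    def test_empty_mu_rejected(self):
        with pytest.raises(ValueError):
            robin_coefficients(1.0, np.array([]))


class TestProfile:
    def test_initial_and_steady(self):
        assert robin_profile(0.5, 0.0, 1.0) == 0.0
        assert robin_profile(0.0, 0.0, 1.0) == 1.0
        # steady interface concentration is 1/(1+alpha_bar)
        assert robin_profile(1.0, 30.0, 1.0) == pytest.approx(0.5, abs=1e-9)
        assert robin_profile(1.0, 30.0, 3.0) == pytest.approx(0.25, abs=1e-9)

    def test_matches_fd_oracle(self):
        assert abs(robin_profile(0.5, 0.1, 1.0) - FD_ROBIN1_X05_T01) < 1e-5
        assert abs(robin_profile(0.5, 0.2, 1.0) - FD_ROBIN1_X05_T02) < 1e-5

    def test_dirichlet_limit_profile(self):
        x = np.linspace(0, 1, 11)
        for t in (0.01, 0.1, 1.0):
            d = np.abs(robin_profile(x, t, 1e8) - conc_profile_dirichlet(x, t))
            assert np.max(d) < 1e-4

    def test_bounded_and_monotone_in_time(self):
        x = np.linspace(0, 1, 21)
        t = np.geomspace(1e-3, 10, 40)
        c = robin_profile(x[None, :], t[:, None], 1.0)
        assert np.all(c >= -1e-9) and np.all(c <= 1 + 1e-9)
        assert np.all(np.diff(c, axis=0) >= -1e-9)


class TestResponse:
    def test_endpoints(self):
        assert robin_response(0.0, 1.0) == 0.0
        assert robin_response(30.0, 1.0) == pytest.approx(1.0, abs=1e-9)

    def test_dirichlet_limit_response(self, t_grid):
        d = np.abs(robin_response(t_grid, 1e8) - response_flux(t_grid))
        assert np.max(d) < 1e-4

    def test_monotone_in_sensitivity(self, t_grid):
        # faster sensor (larger alpha_bar) responds earlier, everywhere
        m = [robin_response(t_grid, ab) for ab in (0.2, 1.0, 5.0)]
        assert np.all(m[1] >= m[0] - 1e-12)
        assert np.all(m[2] >= m[1] - 1e-12)


class TestSteadyState:
    def test_formula_and_zero(self):
        skin = SkinBarrier(D=1.0, L=1.0, C0=2.0)
        # alpha=1 gives alpha_bar=1: m_ss = C0 * alpha / (1 + alpha_bar)
        assert robin_steady_state(skin, 1.0) == pytest.approx(1.0)
        assert robin_steady_state(SkinBarrier(D=1.0, L=1.0, C0=0.0), 1.0) == 0.0
        with pytest.raises(ValueError):
            robin_steady_state(skin, 0.0)

    def test_response_curve(self, skin_kskin):
        curve = robin_response_curve(np.linspace(0, 3, 30), skin_kskin, alpha=2.45e-7)
        assert curve.units == "mol/(cm^2 s)"
        assert curve.steady_state == pytest.approx(
            skin_kskin.C0 * 2.45e-7 / (1 + 2.45e-7 / skin_kskin.permeability)
        )
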