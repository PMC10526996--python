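import numpy as np
import pytest
from hypothesis import given, strategies as st

from dermaflux.domain import SensorKind, SkinBarrier
from dermaflux.series import (
    ResponseCurve,
    conc_profile_dirichlet,
    conc_profile_neumann,
    response_conc,
    response_curve,
    response_flux,
    steady_state_flux,
)

# Finite-difference oracle values, computed once with the independent
# Crank-Nicolson solver at nx=1201, dt_bar=2e-5 (see dermaflux.fdm).
FD_NEUMANN_X1_T01 = 0.05069480852587261
FD_NEUMANN_X1_T025 = 0.31455427959137344
FD_DIRICHLET_X05_T005 = 0.11384434722468806
FD_EXIT_FLUX_T01 = 0.2928985422703534

t_bars = st.floats(min_value=0.0, max_value=20.0, allow_nan=False)
x_bars = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestNeumannProfile:
    def test_initial_condition(self):
        assert conc_profile_neumann(0.7, 0.0) == 0.0
        assert conc_profile_neumann(0.0, 0.0) == 1.0

    def test_uniform_steady_state(self):
        assert conc_profile_neumann(0.5, 10.0) == pytest.approx(1.0, abs=1e-9)

    def test_matches_fd_oracle_at_sensor(self):
        assert abs(conc_profile_neumann(1.0, 0.1) - FD_NEUMANN_X1_T01) < 1e-6

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            conc_profile_neumann(0.5, -0.1)
        with pytest.raises(ValueError):
            conc_profile_neumann(1.5, 0.1)


class TestDirichletProfile:
    def test_sensor_boundary_pinned(self):
        for t in (0.0, 0.01, 0.5, 10.0):
            assert conc_profile_dirichlet(1.0, t) == pytest.approx(0.0, abs=1e-12)

    def test_linear_steady_state(self):
        assert conc_profile_dirichlet(0.25, 10.0) == pytest.approx(0.75, abs=1e-9)

    def test_matches_fd_oracle_midslab(self):
        assert abs(conc_profile_dirichlet(0.5, 0.05) - FD_DIRICHLET_X05_T005) < 1e-6


class TestResponses:
    def test_start_and_steady(self):
        assert response_conc(0.0) == 0.0
        assert response_flux(0.0) == 0.0
        assert response_conc(20.0) == pytest.approx(1.0, abs=1e-9)
        assert response_flux(20.0) == pytest.approx(1.0, abs=1e-9)

    def test_conc_response_is_profile_at_interface(self):
        # the sine series at x_bar=1 and the cos(pi i) form are the same sum
        t = np.array([0.05, 0.1, 0.5, 1.0])
        np.testing.assert_allclose(response_conc(t), conc_profile_neumann(1.0, t), atol=1e-12)

    def test_conc_response_matches_fd_oracle(self):
        assert abs(response_conc(0.25) - FD_NEUMANN_X1_T025) < 1e-6

    def test_flux_response_matches_fd_boundary_gradient(self):
        assert abs(response_flux(0.1) - FD_EXIT_FLUX_T01) < 1e-5

    @given(t=t_bars)
    def test_responses_in_unit_interval(self, t):
        for m in (response_conc(t), response_flux(t)):
            assert -1e-9 <= m <= 1 + 1e-9

    def test_monotone_and_flux_dominates(self, t_grid):
        mc = response_conc(t_grid)
        mf = response_flux(t_grid)
        assert np.all(np.diff(mc) >= -1e-12)
        assert np.all(np.diff(mf) >= -1e-12)
        # the flux-type system is faster everywhere
        assert np.all(mf >= mc - 1e-12)

    def test_truncation_self_consistency(self):
        # tightening the tolerance changes nothing beyond the looser one
        for t in (0.005, 0.05, 0.5):
            assert abs(response_conc(t, tol=1e-8) - response_conc(t, tol=1e-14)) < 1e-8
            assert abs(response_flux(t, tol=1e-8) - response_flux(t, tol=1e-14)) < 1e-8


class TestMaximumPrinciple:
    @pytest.mark.parametrize("profile", [conc_profile_neumann, conc_profile_dirichlet])
    def test_bounded_on_grid(self, profile):
        x = np.linspace(0, 1, 41)
        t = np.concatenate(([0.0], np.geomspace(1e-3, 10, 40)))
        xx, tt = np.meshgrid(x, t)
        c = profile(xx, tt)
        assert np.all(c >= -1e-9) and np.all(c <= 1 + 1e-9)

    @pytest.mark.parametrize("profile", [conc_profile_neumann, conc_profile_dirichlet])
    def test_nondecreasing_in_time(self, profile):
        x = np.linspace(0.0, 1.0, 21)
        t = np.geomspace(1e-3, 10, 50)
        c = profile(x[None, :], t[:, None])
        assert np.all(np.diff(c, axis=0) >= -1e-9)


class TestSteadyStateFlux:
    def test_values(self):
        assert steady_state_flux(SkinBarrier(D=1.0, L=1.0, C0=0.0)) == 0.0
        assert steady_state_flux(SkinBarrier(D=1.0, L=1.0, C0=1.0)) == 1.0
        # WrisTAS patent operating point: 100 mg/dL across k_skin = 5.3e-7 cm/s
        skin = SkinBarrier(D=5.3e-7 * 1.5e-3, L=1.5e-3, C0=2.17e-5)
        assert steady_state_flux(skin) == pytest.approx(1.15e-11, rel=0.01)


class TestResponseCurve:
    def test_factory_units(self, unit_skin):
        t = np.linspace(0, 3, 50)
        conc = response_curve(SensorKind.CONCENTRATION, t, unit_skin)
        flux = response_curve("ideal_flux", t, unit_skin)
        assert conc.units == "mol/cm^3" and conc.steady_state == unit_skin.C0
        assert flux.units == "mol/(cm^2 s)" and flux.steady_state == 1.0

    def test_validation(self, unit_skin):
        with pytest.raises(ValueError):
            ResponseCurve(np.array([0.0, 1.0]), np.array([0.0, 2.0]), 1.0,
                          SensorKind.CONCENTRATION, "mol/cm^3")
        with pytest.raises(ValueError):
            response_curve(SensorKind.ROBIN, np.linspace(0, 1, 5), unit_skin)
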