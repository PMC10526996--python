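"""Eigenfunction solution of the Robin (finite-sensitivity) sensor problem.

A Robin sensor draws an outward flux proportional to the local concentration,
D dc/dx|_{x=L} = -alpha c(L,t). In dimensionless variables the transient
part of the solution separates into modes sin(mu_n x_bar) exp(-mu_n^2 t_bar)
whose eigenvalues are the positive roots of the transcendental condition

    mu cos(mu) + alpha_bar sin(mu) = 0,

one per interval ((n-1/2) pi, n pi). The steady state is the linear profile
v_ss(x_bar) = 1 - alpha_bar x_bar / (1 + alpha_bar), and the projection
coefficients b_n expand the negated steady state in the (non-orthonormal but
orthogonal) Sturm-Liouville eigenbasis so the initial condition c_bar = 0 is
met. As alpha_bar -> infinity the eigenvalues approach n*pi and the system
degenerates to the Dirichlet (ideal flux) problem; as alpha_bar -> 0 they
approach (n-1/2)*pi and the temporal behaviour is that of the Neumann
(concentration-type) problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from dermaflux.domain import SkinBarrier, alpha_bar as _alpha_bar_of
from dermaflux.series import T_BAR_SERIES_MIN, ResponseCurve
from dermaflux.domain import SensorKind

__all__ = [
    "DEFAULT_PROFILE_MODES",
    "DEFAULT_RESPONSE_MODES",
    "RobinEigensystem",
    "robin_eigensystem",
    "robin_eigenvalues",
    "robin_coefficients",
    "robin_profile",
    "robin_response",
    "robin_response_curve",
    "robin_steady_state",
    "steady_profile",
]

DEFAULT_PROFILE_MODES = 200
DEFAULT_RESPONSE_MODES = 50


@dataclass(frozen=True)
class RobinEigensystem:
    """Eigenvalues and projection coefficients for one alpha_bar."""

    alpha_bar: float
    mu: np.ndarray
    b: np.ndarray

    @property
    def n_modes(self) -> int:
        return len(self.mu)

    def residuals(self) -> np.ndarray:
        """Eigencondition residual mu*cos(mu) + alpha_bar*sin(mu), scaled.

        Scaled by max(mu, alpha_bar) per mode so the tolerance is meaningful
        across the whole alpha_bar range.
        """
        raw = self.mu * np.cos(self.mu) + self.alpha_bar * np.sin(self.mu)
        return raw / np.maximum(self.mu, self.alpha_bar)


def robin_eigenvalues(alpha_bar: float, n_modes: int) -> np.ndarray:
    """First *n_modes* positive roots of mu*cos(mu) + alpha_bar*sin(mu) = 0.

    The n-th root lies strictly inside ((n-1/2)*pi, n*pi) for alpha_bar > 0;
    each is bracketed there and refined by Brent's method. For the limiting
    Neumann/Dirichlet problems use the dedicated series solutions.
    """
    if alpha_bar <= 0:
        raise ValueError("alpha_bar must be > 0; use the Neumann/Dirichlet solvers for the limits")
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")

    def f(mu: float) -> float:
        return mu * np.cos(mu) + alpha_bar * np.sin(mu)

    eps = 1e-13
    roots = np.empty(n_modes)
    for n in range(1, n_modes + 1):
        lo = (n - 0.5) * np.pi * (1 + eps)
        hi = n * np.pi * (1 - eps)
        roots[n - 1] = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
    return roots


def steady_profile(x_bar, alpha_bar: float):
    """Dimensionless steady-state profile 1 - alpha_bar*x_bar/(1+alpha_bar)."""
    x = np.asarray(x_bar, dtype=float)
    out = 1.0 - alpha_bar * x / (1.0 + alpha_bar)
    return out if out.ndim else float(out)


def robin_coefficients(alpha_bar: float, mu: np.ndarray) -> np.ndarray:
    """Projection coefficients b_n of the negated steady state.

    b_n = -<v_ss, sin(mu_n x)> / <sin(mu_n x), sin(mu_n x)> on x in [0, 1],
    with the inner products in closed form:

        int_0^1 sin(mu x) dx        = (1 - cos mu)/mu
        int_0^1 x sin(mu x) dx      = (sin mu - mu cos mu)/mu^2
        int_0^1 sin^2(mu x) dx      = 1/2 - sin(2 mu)/(4 mu)
    """
    mu = np.asarray(mu, dtype=float)
    if mu.size == 0:
        raise ValueError("mu must contain at least one eigenvalue")
    s = alpha_bar / (1.0 + alpha_bar)
    num = (1.0 - np.cos(mu)) / mu - s * (np.sin(mu) - mu * np.cos(mu)) / mu**2
    den = 0.5 - np.sin(2.0 * mu) / (4.0 * mu)
    return -num / den


def robin_eigensystem(alpha_bar: float, n_modes: int = DEFAULT_PROFILE_MODES) -> RobinEigensystem:
    """Solve the eigenproblem and projection for one dimensionless sensitivity."""
    mu = robin_eigenvalues(alpha_bar, n_modes)
    b = robin_coefficients(alpha_bar, mu)
    return RobinEigensystem(alpha_bar=alpha_bar, mu=mu, b=b)


def robin_profile(x_bar, t_bar, alpha_bar: float, n_modes: int = DEFAULT_PROFILE_MODES,
                  eigensystem: RobinEigensystem | None = None):
    """Dimensionless Robin concentration profile c_bar(x_bar, t_bar).

    Sum of the decaying eigenmodes plus the linear steady state. At
    t_bar = 0 the exact initial condition (zero, except the unit blood
    boundary) is returned rather than the slowly converging series.
    """
    x = np.asarray(x_bar, dtype=float)
    t = np.asarray(t_bar, dtype=float)
    if np.any(t < 0):
        raise ValueError("dimensionless time must be >= 0")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("dimensionless position must lie in [0, 1]")
    es = eigensystem if eigensystem is not None else robin_eigensystem(alpha_bar, n_modes)

    x, t = np.broadcast_arrays(x, t)
    out = np.empty(x.shape, dtype=float)
    early = t < T_BAR_SERIES_MIN
    out[early] = np.where(x[early] == 0.0, 1.0, 0.0)
    late = ~early
    if np.any(late):
        xl, tl = x[late], t[late]
        decay = np.exp(-np.outer(tl, es.mu**2))
        shape = np.sin(np.outer(xl, es.mu))
        out[late] = steady_profile(xl, es.alpha_bar) + np.einsum(
            "jk,jk,k->j", decay, shape, es.b
        )
    return out if out.ndim else float(out)


def robin_response(t_bar, alpha_bar: float, n_modes: int = DEFAULT_RESPONSE_MODES,
                   eigensystem: RobinEigensystem | None = None):
    """Normalized Robin sensor step response.

    m_bar(t_bar) = 1 + (1 + alpha_bar) * sum_n b_n sin(mu_n) exp(-mu_n^2
    t_bar); it rises from 0 (convention at t_bar = 0) to 1, always between
    the concentration-type and ideal-flux responses.
    """
    es = eigensystem if eigensystem is not None else robin_eigensystem(alpha_bar, n_modes)
    t = np.asarray(t_bar, dtype=float)
    if np.any(t < 0):
        raise ValueError("dimensionless time must be >= 0")
    t_flat = np.atleast_1d(t).astype(float)
    out = np.zeros(t_flat.shape, dtype=float)
    late = t_flat >= T_BAR_SERIES_MIN
    if np.any(late):
        weights = (1.0 + es.alpha_bar) * es.b * np.sin(es.mu)
        decay = np.exp(-np.outer(t_flat[late], es.mu**2))
        out[late] = 1.0 + decay @ weights
    out = out.reshape(t.shape) if t.ndim else out[0]
    return out if np.ndim(out) else float(out)


def robin_steady_state(skin: SkinBarrier, alpha: float) -> float:
    """Steady-state Robin sensor flux C0*alpha/(1+alpha_bar), mol cm^-2 s^-1."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0 for a Robin sensor")
    ab = _alpha_bar_of(alpha, skin)
    return skin.C0 * alpha / (1.0 + ab)


def robin_response_curve(t_bar, skin: SkinBarrier, alpha: float,
                         n_modes: int = DEFAULT_RESPONSE_MODES) -> ResponseCurve:
    """Sample the normalized Robin response as a :class:`ResponseCurve`."""
    ab = _alpha_bar_of(alpha, skin)
    t = np.asarray(t_bar, dtype=float)
    m = np.clip(robin_response(t, ab, n_modes=n_modes), 0.0, 1.0)
    return ResponseCurve(
        t, m, steady_state=robin_steady_state(skin, alpha),
        sensor_kind=SensorKind.ROBIN, units="mol/(cm^2 s)",
    )
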