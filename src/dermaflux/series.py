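"""Closed-form step responses for concentration- and ideal-flux-type sensors.

Separation of variables on the diffusion equation dc/dt = D d2c/dx2 over the
skin slab, with a unit concentration step at the blood side (x_bar = 0) and
either a Neumann (zero flux; concentration-type sensor) or Dirichlet (zero
concentration; ideal flux-type sensor) condition at the sensor side
(x_bar = 1). All quantities here are dimensionless: x_bar = x/L,
t_bar = t*D/L^2, c_bar = c/C0, and responses are normalized by their
steady-state values so that m_bar rises monotonically from 0 to 1.

The eigenfunction series converge exponentially for t_bar > 0 but
non-uniformly as t_bar -> 0 (the step discontinuity); below T_BAR_SERIES_MIN
the exact initial-condition values are returned instead of summing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dermaflux.domain import SensorKind, SkinBarrier

__all__ = [
    "MAX_TERMS",
    "T_BAR_SERIES_MIN",
    "ResponseCurve",
    "conc_profile_dirichlet",
    "conc_profile_neumann",
    "dirichlet_decay_rate",
    "neumann_decay_rate",
    "response_conc",
    "response_curve",
    "response_flux",
    "steady_state_flux",
]

#: Below this dimensionless time the series are not summed; the exact
#: initial/boundary-condition values are returned instead.
T_BAR_SERIES_MIN = 1e-4

#: Hard cap on retained eigenmodes.
MAX_TERMS = 10_000


def neumann_decay_rate(i):
    """Dimensionless decay rate of Neumann series mode *i* (1-based).

    Mode i carries exp(-neumann_decay_rate(i) * t_bar) with rate
    pi^2 (2i-1)^2 / 4; mode 1 sets the concentration sensor's timescale.
    """
    k = 2.0 * np.asarray(i, dtype=float) - 1.0
    return (np.pi * k / 2.0) ** 2


def dirichlet_decay_rate(i):
    """Dimensionless decay rate pi^2 i^2 of Dirichlet series mode *i* (1-based)."""
    return (np.pi * np.asarray(i, dtype=float)) ** 2


@dataclass(frozen=True)
class ResponseCurve:
    """Sampled normalized step response with its dimensional steady state.

    ``steady_state`` is in mol/cm^3 for concentration sensors and in
    mol cm^-2 s^-1 for flux-measuring (Dirichlet or Robin) sensors; the
    ``units`` tag records which.
    """

    t_bar: np.ndarray
    m_bar: np.ndarray
    steady_state: float
    sensor_kind: SensorKind
    units: str

    def __post_init__(self) -> None:
        t = np.asarray(self.t_bar, dtype=float)
        m = np.asarray(self.m_bar, dtype=float)
        object.__setattr__(self, "t_bar", t)
        object.__setattr__(self, "m_bar", m)
        if t.shape != m.shape:
            raise ValueError("t_bar and m_bar must have matching shapes")
        if np.any(t < 0):
            raise ValueError("dimensionless times must be >= 0")
        if np.any(m < -1e-9) or np.any(m > 1 + 1e-9):
            raise ValueError("normalized response must lie in [0, 1]")


def _validate(x_bar: np.ndarray, t_bar: np.ndarray) -> None:
    if np.any(t_bar < 0):
        raise ValueError("dimensionless time must be >= 0")
    if np.any((x_bar < 0) | (x_bar > 1)):
        raise ValueError("dimensionless position must lie in [0, 1]")


def _n_terms(t_min: float, tol: float, half_mode: bool) -> int:
    """Modes needed so the first omitted term is below *tol* at t_bar=t_min.

    Terms decay like exp(-pi^2 t k^2 / 4) with k = 2i-1 for the Neumann
    (half-mode) series and like exp(-pi^2 t i^2) for the Dirichlet one.
    """
    log_tol = -np.log(tol)
    if half_mode:
        k = np.sqrt(4.0 * log_tol / (np.pi**2 * t_min))
        n = int(np.ceil((k + 1.0) / 2.0))
    else:
        n = int(np.ceil(np.sqrt(log_tol / (np.pi**2 * t_min))))
    return min(max(n, 2), MAX_TERMS)


def conc_profile_neumann(x_bar, t_bar, tol: float = 1e-12):
    """Dimensionless concentration profile with a zero-flux sensor boundary.

    c_bar(x_bar, t_bar) = 1 - (4/pi) * sum_{i>=1} exp(-pi^2 t_bar (2i-1)^2/4)
    * sin(pi x_bar (2i-1)/2) / (2i-1); the steady state is the uniform
    blood concentration.
    """
    x = np.asarray(x_bar, dtype=float)
    t = np.asarray(t_bar, dtype=float)
    _validate(x, t)
    x, t = np.broadcast_arrays(x, t)
    out = np.empty(x.shape, dtype=float)

    early = t < T_BAR_SERIES_MIN
    out[early] = np.where(x[early] == 0.0, 1.0, 0.0)

    late = ~early
    if np.any(late):
        xl, tl = x[late], t[late]
        n = _n_terms(float(tl.min()), tol, half_mode=True)
        modes = np.arange(1, n + 1)
        k = 2.0 * modes - 1.0  # odd mode numbers
        decay = np.exp(-np.outer(tl, neumann_decay_rate(modes)))
        shape = np.sin(np.pi * np.outer(xl, k) / 2.0)
        out[late] = 1.0 - (4.0 / np.pi) * np.einsum("jk,jk,k->j", decay, shape, 1.0 / k)
    return out if out.ndim else float(out)


def response_conc(t_bar, tol: float = 1e-12):
    """Normalized step response of a concentration-type (Neumann) sensor.

    Equals the profile evaluated at the sensor interface x_bar = 1; rises
    monotonically from 0 to the steady state 1.
    """
    return conc_profile_neumann(1.0, t_bar, tol=tol)


def conc_profile_dirichlet(x_bar, t_bar, tol: float = 1e-12):
    """Dimensionless concentration profile with a perfectly consuming sensor.

    c_bar(x_bar, t_bar) = 1 - x_bar - (2/pi) * sum_{i>=1}
    exp(-pi^2 t_bar i^2) * sin(pi x_bar i) / i; the steady state is the
    linear profile 1 - x_bar and the sensor interface is pinned at zero.
    """
    x = np.asarray(x_bar, dtype=float)
    t = np.asarray(t_bar, dtype=float)
    _validate(x, t)
    x, t = np.broadcast_arrays(x, t)
    out = np.empty(x.shape, dtype=float)

    early = t < T_BAR_SERIES_MIN
    out[early] = np.where(x[early] == 0.0, 1.0, 0.0)

    late = ~early
    if np.any(late):
        xl, tl = x[late], t[late]
        n = _n_terms(float(tl.min()), tol, half_mode=False)
        i = np.arange(1.0, n + 1)
        decay = np.exp(-np.outer(tl, dirichlet_decay_rate(i)))
        shape = np.sin(np.pi * np.outer(xl, i))
        out[late] = 1.0 - xl - (2.0 / np.pi) * np.einsum("jk,jk,k->j", decay, shape, 1.0 / i)
    return out if out.ndim else float(out)


def response_flux(t_bar, tol: float = 1e-12):
    """Normalized step response of an ideal flux-type (Dirichlet) sensor.

    m_bar(t_bar) = 1 + 2 * sum_{i>=1} (-1)^i exp(-pi^2 t_bar i^2), the exit
    flux -D dc/dx at x_bar = 1 normalized by its steady state C0*D/L. At
    t_bar = 0 no analyte has crossed the slab, so m_bar = 0 by continuity
    (the series itself is non-uniformly convergent there).
    """
    t = np.asarray(t_bar, dtype=float)
    if np.any(t < 0):
        raise ValueError("dimensionless time must be >= 0")
    t_flat = np.atleast_1d(t).astype(float)
    out = np.zeros(t_flat.shape, dtype=float)

    late = t_flat >= T_BAR_SERIES_MIN
    if np.any(late):
        tl = t_flat[late]
        n = _n_terms(float(tl.min()), tol, half_mode=False)
        i = np.arange(1.0, n + 1)
        sign = np.where(np.arange(1, n + 1) % 2 == 0, 1.0, -1.0)  # cos(pi*i)
        decay = np.exp(-np.outer(tl, dirichlet_decay_rate(i)))
        out[late] = 1.0 + 2.0 * decay @ sign
    out = out.reshape(t.shape) if t.ndim else out[0]
    return out if np.ndim(out) else float(out)


def steady_state_flux(skin: SkinBarrier) -> float:
    """Steady-state exit flux C0*D/L of the Dirichlet system, mol cm^-2 s^-1."""
    return skin.C0 * skin.D / skin.L


def response_curve(kind: SensorKind | str, t_bar, skin: SkinBarrier, tol: float = 1e-12) -> ResponseCurve:
    """Sample the normalized response of a Neumann or Dirichlet sensor system.

    Robin sensors are handled by :func:`dermaflux.robin.robin_response_curve`.
    """
    kind = SensorKind(kind)
    t = np.asarray(t_bar, dtype=float)
    if kind is SensorKind.CONCENTRATION:
        m = np.clip(response_conc(t, tol=tol), 0.0, 1.0)
        return ResponseCurve(t, m, steady_state=skin.C0, sensor_kind=kind, units="mol/cm^3")
    if kind is SensorKind.IDEAL_FLUX:
        m = np.clip(response_flux(t, tol=tol), 0.0, 1.0)
        return ResponseCurve(
            t, m, steady_state=steady_state_flux(skin), sensor_kind=kind, units="mol/(cm^2 s)"
        )
    raise ValueError("use dermaflux.robin.robin_response_curve for Robin sensors")
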