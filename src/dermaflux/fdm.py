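"""Finite-difference verification solver for the skin-slab diffusion problem.

An independent numerical route to the same dimensionless problem the series
solutions answer analytically: dc/dt_bar = d2c/dx_bar^2 on [0, 1], blood
boundary pinned at c_bar = 1, sensor boundary Neumann, Dirichlet, or Robin.
Space is discretized with second-order central differences (ghost nodes for
the flux-type boundaries so the boundary remains second-order accurate);
time marches with Crank-Nicolson, preceded by a few damped backward-Euler
half-steps to suppress the oscillations the concentration step at the blood
boundary would otherwise excite (Rannacher start-up).

This module is the oracle the test suite holds every analytic solution
against; it shares no code with the series implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "FiniteDifferenceField",
    "boundary_flux",
    "convergence_study",
    "solve_pde",
]

_BOUNDARY_KINDS = ("neumann", "dirichlet", "robin")


@dataclass(frozen=True)
class FiniteDifferenceField:
    """Solved dimensionless concentration field c_bar(t_bar, x_bar)."""

    x_bar: np.ndarray          # uniform grid on [0, 1], nx nodes
    t_bar: np.ndarray          # recorded times
    c_bar: np.ndarray          # (n_times, nx)
    boundary: str
    alpha_bar: float | None
    nx: int
    dt_bar: float

    def at(self, t_index: int) -> np.ndarray:
        return self.c_bar[t_index]


def _build_operator(nx: int, h: float, boundary: str, alpha_bar: float | None):
    """Second-order semi-discrete Laplacian rows for the unknown nodes.

    Unknowns are nodes 1..nx-2 for Dirichlet (both boundaries pinned) and
    1..nx-1 for Neumann/Robin (sensor node evolves via its ghost-node row).
    Returns (lower, diag, upper, source) where source carries the pinned
    blood node's contribution.
    """
    if boundary == "dirichlet":
        m = nx - 2
    else:
        m = nx - 1
    lower = np.full(m, 1.0 / h**2)
    diag = np.full(m, -2.0 / h**2)
    upper = np.full(m, 1.0 / h**2)
    if boundary != "dirichlet":
        ab = alpha_bar if boundary == "robin" else 0.0
        # ghost node: c_ghost = c_{n-2} - 2 h alpha_bar c_{n-1}
        lower[m - 1] = 2.0 / h**2
        diag[m - 1] = -(2.0 + 2.0 * h * ab) / h**2
    source = np.zeros(m)
    source[0] = 1.0 / h**2  # blood node c_bar(0) = 1
    return lower, diag, upper, source


def _march(c, lower, diag, upper, source, dt, n_steps, theta):
    """theta-scheme steps of dc/dt = A c + source with a tridiagonal A."""
    m = len(c)
    # banded form of (I - theta dt A)
    band = np.zeros((3, m))
    band[0, 1:] = -theta * dt * upper[:-1]
    band[1, :] = 1.0 - theta * dt * diag
    band[2, :-1] = -theta * dt * lower[1:]
    w = (1.0 - theta) * dt
    for _ in range(n_steps):
        rhs = c + w * (
            diag * c
            + np.concatenate(([0.0], lower[1:] * c[:-1]))
            + np.concatenate((upper[:-1] * c[1:], [0.0]))
        ) + dt * source
        c = solve_banded((1, 1), band, rhs)
    return c


def solve_pde(
    boundary: str,
    t_bar: np.ndarray | list[float],
    alpha_bar: float | None = None,
    nx: int = 601,
    dt_bar: float = 5e-5,
) -> FiniteDifferenceField:
    """Solve the dimensionless step-response problem numerically.

    Parameters
    ----------
    boundary : {"neumann", "dirichlet", "robin"}
        Sensor-side boundary condition.
    t_bar : array-like
        Times at which to record the field; each is rounded to the nearest
        whole number of time steps.
    alpha_bar : float, optional
        Dimensionless sensitivity; required for (and only for) Robin.
    nx : int
        Number of uniformly spaced spatial nodes including both boundaries.
    dt_bar : float
        Time-step size.
    """
    if boundary not in _BOUNDARY_KINDS:
        raise ValueError(f"boundary must be one of {_BOUNDARY_KINDS}, got {boundary!r}")
    if boundary == "robin":
        if alpha_bar is None or alpha_bar <= 0:
            raise ValueError("Robin boundary requires alpha_bar > 0")
    elif alpha_bar is not None:
        raise ValueError(f"alpha_bar is only meaningful for the Robin boundary")
    if nx < 11:
        raise ValueError(f"nx must be >= 11 for a meaningful grid, got {nx}")
    if dt_bar <= 0:
        raise ValueError(f"dt_bar must be > 0, got {dt_bar}")
    t_req = np.sort(np.asarray(t_bar, dtype=float))
    if t_req.size == 0 or np.any(t_req < 0):
        raise ValueError("t_bar must be non-empty with all entries >= 0")

    h = 1.0 / (nx - 1)
    x = np.linspace(0.0, 1.0, nx)
    lower, diag, upper, source = _build_operator(nx, h, boundary, alpha_bar)
    m = len(diag)

    n_rannacher = 4  # backward-Euler half-steps damping the initial step
    c = np.zeros(m)
    fields = np.empty((t_req.size, nx))
    steps_done = 0
    started = False
    for k, t in enumerate(t_req):
        target = int(round(t / dt_bar))
        if t > 0 and not started:
            warm = min(n_rannacher, 2 * target)
            c = _march(c, lower, diag, upper, source, dt_bar / 2.0, warm, theta=1.0)
            steps_done = warm // 2  # two half-steps advance one full step
            started = True
        c = _march(c, lower, diag, upper, source, dt_bar, max(target - steps_done, 0), theta=0.5)
        steps_done = max(target, steps_done)

        row = np.empty(nx)
        row[0] = 1.0
        if boundary == "dirichlet":
            row[1:-1] = c
            row[-1] = 0.0
        else:
            row[1:] = c
        if t == 0.0:
            row[1:] = 0.0
        fields[k] = row

    return FiniteDifferenceField(
        x_bar=x, t_bar=t_req, c_bar=fields, boundary=boundary,
        alpha_bar=alpha_bar, nx=nx, dt_bar=dt_bar,
    )


def boundary_flux(field: FiniteDifferenceField) -> np.ndarray:
    """Dimensionless exit flux -dc_bar/dx_bar at the sensor boundary.

    One-sided second-order gradient estimate; already normalized by the
    steady-state scale C0*D/L by virtue of the nondimensional variables.
    """
    h = field.x_bar[1] - field.x_bar[0]
    c = field.c_bar
    grad = (3.0 * c[:, -1] - 4.0 * c[:, -2] + c[:, -3]) / (2.0 * h)
    return -grad


def convergence_study(
    boundary: str,
    nx_values: list[int] = (41, 81, 161),
    t_check: float = 0.1,
    alpha_bar: float | None = None,
) -> float:
    """Observed spatial convergence order from successive grid refinements.

    Solves at each grid with a time step proportional to h^2 so the
    second-order time error refines alongside, then compares successive
    solutions on the shared coarse nodes (Richardson-style); returns
    log2 of the error ratio, which should be close to 2.
    """
    nx_values = sorted(nx_values)
    if len(nx_values) < 3:
        raise ValueError("need at least 3 grid refinements")
    sols = []
    for nx in nx_values:
        h = 1.0 / (nx - 1)
        dt = t_check / max(int(np.ceil(t_check / (0.2 * h**2))), 1)
        f = solve_pde(boundary, [t_check], alpha_bar=alpha_bar, nx=nx, dt_bar=dt)
        sols.append((f.x_bar, f.c_bar[0]))

    errors = []
    for (xc, cc), (xf, cf) in zip(sols[:-1], sols[1:]):
        fine_on_coarse = np.interp(xc, xf, cf)
        # refinements share nodes when (nx-1) ratios are integer; interp is exact there
        errors.append(np.max(np.abs(cc - fine_on_coarse)))
    orders = [np.log2(e1 / e2) for e1, e2 in zip(errors[:-1], errors[1:])]
    return float(np.mean(orders))
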