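"""Response-timescale metrics and sensor-speed classification.

Two complementary timescale definitions are implemented for the step
response of a skin-plus-sensor system:

* the *leading-term* timescale, the reciprocal decay rate of the slowest
  eigenmode of the response series (tau = L^2/(D * lambda_1) with lambda_1
  the mode-1 dimensionless rate), and
* the *integrated-intercept* timescale t_bar* = int_0^inf (1 - m_bar) dt_bar,
  the x-intercept of the asymptote of the time-integrated normalized
  response (the diffusion "lag time" of the membrane-permeation literature).

By either metric an ideal flux-type sensor responds faster than a
concentration-type one through the same skin: the leading timescales differ
by a factor of exactly 4, the integrated intercepts by a factor of 3
(1/2 versus 1/6). A Robin sensor falls between the two, approaching either
limit as its dimensionless sensitivity alpha_bar goes to 0 or infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dermaflux.domain import SensorKind, SkinBarrier
from dermaflux.robin import robin_eigensystem, robin_eigenvalues
from dermaflux.series import MAX_TERMS, dirichlet_decay_rate, neumann_decay_rate

__all__ = [
    "CLASSIFY_FLUX_THRESHOLD",
    "CLASSIFY_CONC_THRESHOLD",
    "TimescaleReport",
    "classify_sensor",
    "integrated_intercept",
    "leading_timescale",
    "robin_leading_timescale",
    "timescale_report",
]

#: Default alpha_bar above which a sensor is effectively ideal-flux-type and
#: below which it is effectively concentration-type in its time response.
#: Chosen as "an order of magnitude away from 1" on either side; both are
#: configurable in :func:`classify_sensor`.
CLASSIFY_FLUX_THRESHOLD = 10.0
CLASSIFY_CONC_THRESHOLD = 0.1


@dataclass(frozen=True)
class TimescaleReport:
    """Side-by-side timescale metrics for one skin barrier."""

    tau_flux_s: float
    tau_conc_s: float
    tau_ratio: float
    intercept_flux: float
    intercept_conc: float
    intercept_ratio: float
    skin: SkinBarrier

    def as_dict(self) -> dict:
        return {
            "tau_flux_s": self.tau_flux_s,
            "tau_conc_s": self.tau_conc_s,
            "tau_ratio": self.tau_ratio,
            "intercept_flux": self.intercept_flux,
            "intercept_conc": self.intercept_conc,
            "intercept_ratio": self.intercept_ratio,
        }


def leading_timescale(kind: SensorKind | str, skin: SkinBarrier) -> float:
    """Slowest-mode time constant of the step response, in seconds.

    Reads the mode-1 dimensionless decay rate off the implemented response
    series and converts with the diffusion time L^2/D. Robin sensors need
    their eigenvalue and are handled by :func:`robin_leading_timescale`.
    """
    kind = SensorKind(kind)
    if kind is SensorKind.CONCENTRATION:
        rate = float(neumann_decay_rate(1))
    elif kind is SensorKind.IDEAL_FLUX:
        rate = float(dirichlet_decay_rate(1))
    else:
        raise ValueError("Robin sensors: use robin_leading_timescale(alpha_bar, skin)")
    return skin.diffusion_time / rate


def robin_leading_timescale(alpha_bar: float, skin: SkinBarrier) -> float:
    """Slowest-mode time constant L^2/(D mu_1^2) of a Robin sensor system, s.

    Strictly between the ideal-flux value L^2/(D pi^2) and the
    concentration-sensor value 4 L^2/(D pi^2) for any finite alpha_bar > 0.
    """
    mu1 = float(robin_eigenvalues(alpha_bar, 1)[0])
    return skin.diffusion_time / mu1**2


def integrated_intercept(kind: SensorKind | str, alpha_bar: float | None = None,
                         tol: float = 1e-12) -> float:
    """Integrated-intercept timescale t_bar* = int_0^inf (1 - m_bar) dt_bar.

    Each exponential in the response series integrates in closed form, so
    the intercept is a term-wise sum truncated once terms drop below *tol*
    (the alternating Neumann/Dirichlet sums are cut where the first omitted
    term is below *tol*). Values are dimensionless; multiply by L^2/D for
    seconds.
    """
    kind = SensorKind(kind)
    if kind is SensorKind.IDEAL_FLUX:
        # m_bar = 1 + 2 sum (-1)^i exp(-pi^2 i^2 t); each term integrates to
        # 2 (-1)^(i+1) / (pi^2 i^2)
        n = int(np.ceil(np.sqrt(2.0 / (np.pi**2 * tol))))
        i = np.arange(1.0, n + 1)
        terms = 2.0 * (-1.0) ** (i + 1) / dirichlet_decay_rate(i)
        return float(terms.sum())
    if kind is SensorKind.CONCENTRATION:
        # terms (4/pi) (-1)^(i+1)/(2i-1) * 4/(pi^2 (2i-1)^2)
        n = int(np.ceil((np.cbrt(16.0 / (np.pi**3 * tol)) + 1.0) / 2.0))
        i = np.arange(1.0, n + 1)
        k = 2.0 * i - 1.0
        terms = (4.0 / np.pi) * (-1.0) ** (i + 1) / (k * neumann_decay_rate(i))
        return float(terms.sum())
    # Robin: t_bar* = -(1+ab) sum b_n sin(mu_n) / mu_n^2, terms decaying ~ n^-3
    if alpha_bar is None or alpha_bar <= 0:
        raise ValueError("Robin intercept requires alpha_bar > 0")
    n_modes = 200
    while True:
        es = robin_eigensystem(alpha_bar, n_modes)
        terms = -(1.0 + alpha_bar) * es.b * np.sin(es.mu) / es.mu**2
        if abs(terms[-1]) < tol or n_modes >= MAX_TERMS:
            return float(terms.sum())
        n_modes = min(n_modes * 4, MAX_TERMS)


def classify_sensor(alpha_bar: float,
                    flux_threshold: float = CLASSIFY_FLUX_THRESHOLD,
                    conc_threshold: float = CLASSIFY_CONC_THRESHOLD) -> dict:
    """Place a sensor on the concentration-type/Robin/flux-type spectrum.

    A sensitivity much larger than the skin permeability (alpha_bar above
    *flux_threshold*) makes the system behave as an ideal flux-type sensor;
    much smaller (below *conc_threshold*) gives the temporal response of a
    concentration sensor; anything between is genuinely Robin.
    """
    if alpha_bar < 0:
        raise ValueError("alpha_bar must be >= 0")
    if alpha_bar >= flux_threshold:
        label = "ideal-flux-like"
    elif alpha_bar <= conc_threshold:
        label = "concentration-like"
    else:
        label = "robin"
    return {"label": label, "alpha_bar": alpha_bar}


def timescale_report(skin: SkinBarrier) -> TimescaleReport:
    """Both timescale metrics and their ratios for one skin barrier."""
    tau_flux = leading_timescale(SensorKind.IDEAL_FLUX, skin)
    tau_conc = leading_timescale(SensorKind.CONCENTRATION, skin)
    icpt_flux = integrated_intercept(SensorKind.IDEAL_FLUX)
    icpt_conc = integrated_intercept(SensorKind.CONCENTRATION)
    return TimescaleReport(
        tau_flux_s=tau_flux,
        tau_conc_s=tau_conc,
        tau_ratio=tau_conc / tau_flux,
        intercept_flux=icpt_flux,
        intercept_conc=icpt_conc,
        intercept_ratio=icpt_conc / icpt_flux,
        skin=skin,
    )
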