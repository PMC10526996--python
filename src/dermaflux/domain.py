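"""Physical parameter containers, unit conversions, and nondimensionalization.

Internal unit convention is cm / s / mol throughout (skin permeabilities and
electrode rate constants are conventionally quoted in cm/s, concentrations in
mol/cm^3). Converters at the boundary accept the units field data usually
arrive in: micrometres for skin thickness, hours for timescales, mg/dL and
umol/L for concentrations, nA and uA for electrode currents.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "FARADAY_S_A_PER_MOL",
    "AmperometricCalibration",
    "DimensionlessGrid",
    "SensorKind",
    "SensorSpec",
    "SkinBarrier",
    "alpha_bar",
    "hours_to_seconds",
    "mass_concentration_to_molar_volume",
    "micromolar_to_molar_volume",
    "microns_to_cm",
    "nondimensionalize_time",
    "permeability",
    "redimensionalize_time",
    "seconds_to_hours",
]

#: Faraday constant in s*A/mol, to the precision customarily used in
#: amperometric sensitivity arithmetic.
FARADAY_S_A_PER_MOL = 9.64e4


class SensorKind(str, enum.Enum):
    """Boundary-condition class of a transdermal sensor."""

    CONCENTRATION = "concentration"  # Neumann: zero flux at skin/sensor interface
    IDEAL_FLUX = "ideal_flux"        # Dirichlet: zero concentration at interface
    ROBIN = "robin"                  # flux proportional to local concentration


@dataclass(frozen=True)
class SkinBarrier:
    """Homogeneous rate-limiting skin slab.

    Parameters
    ----------
    D : float
        Diffusion coefficient of the analyte in the slab, cm^2/s.
    L : float
        Slab thickness (stratum corneum), cm.
    C0 : float
        Blood-side analyte concentration step, mol/cm^3.
    """

    D: float
    L: float
    C0: float = 1.0

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"diffusion coefficient D must be > 0, got {self.D}")
        if self.L <= 0:
            raise ValueError(f"thickness L must be > 0, got {self.L}")
        if self.C0 < 0:
            raise ValueError(f"concentration step C0 must be >= 0, got {self.C0}")

    @property
    def permeability(self) -> float:
        """Mass-transfer coefficient k_skin = D/L, cm/s."""
        return self.D / self.L

    @property
    def diffusion_time(self) -> float:
        """Characteristic diffusion time L^2/D, s."""
        return self.L**2 / self.D


@dataclass(frozen=True)
class SensorSpec:
    """Sensor class and (for Robin sensors) its rate constant alpha in cm/s."""

    kind: SensorKind
    alpha: float | None = None

    def __post_init__(self) -> None:
        kind = SensorKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is SensorKind.ROBIN:
            if self.alpha is None or self.alpha <= 0:
                raise ValueError("Robin sensors require alpha > 0 (cm/s)")

    def alpha_bar(self, skin: SkinBarrier) -> float:
        """Dimensionless sensitivity alpha/(D/L) relative to *skin*."""
        if self.kind is SensorKind.CONCENTRATION:
            return 0.0
        if self.kind is SensorKind.IDEAL_FLUX:
            return float("inf")
        assert self.alpha is not None
        return alpha_bar(self.alpha, skin)


@dataclass(frozen=True)
class DimensionlessGrid:
    """Dimensionless evaluation grid: times tD/L^2 and positions x/L."""

    t_bar: tuple[float, ...]
    x_bar: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.t_bar):
            raise ValueError("all dimensionless times must be >= 0")
        if any(not 0.0 <= x <= 1.0 for x in self.x_bar):
            raise ValueError("all dimensionless positions must lie in [0, 1]")


@dataclass(frozen=True)
class AmperometricCalibration:
    """Electrode calibration point for deducing a mass-transport coefficient.

    Attributes
    ----------
    current : float
        Steady calibration current, A.
    calib_concentration : float
        Analyte concentration during calibration, mol/cm^3.
    electrons_per_molecule : int
        Electrons liberated per analyte molecule oxidised.
    area : float
        Active electrode area, cm^2.
    faraday : float
        Faraday constant, s*A/mol.
    molecular_weight : float | None
        g/mol; retained so mass-unit inputs can be traced back.
    """

    current: float
    calib_concentration: float
    electrons_per_molecule: int
    area: float
    faraday: float = FARADAY_S_A_PER_MOL
    molecular_weight: float | None = None

    def __post_init__(self) -> None:
        if self.current < 0:
            raise ValueError("current must be >= 0")
        for name in ("calib_concentration", "electrons_per_molecule", "area", "faraday"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.molecular_weight is not None and self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be > 0")


def nondimensionalize_time(t: float, skin: SkinBarrier) -> float:
    """Convert dimensional time t (s) to t_bar = t*D/L^2."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    return t * skin.D / skin.L**2


def redimensionalize_time(t_bar: float, skin: SkinBarrier) -> float:
    """Convert dimensionless time t_bar back to seconds."""
    if t_bar < 0:
        raise ValueError(f"dimensionless time must be >= 0, got {t_bar}")
    return t_bar * skin.L**2 / skin.D


def permeability(skin: SkinBarrier) -> float:
    """Skin permeability (mass-transfer coefficient) k_skin = D/L, cm/s."""
    return skin.permeability


def alpha_bar(alpha: float, skin: SkinBarrier) -> float:
    """Dimensionless sensor sensitivity alpha_bar = alpha*L/D = alpha/k_skin."""
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    return alpha / skin.permeability


def mass_concentration_to_molar_volume(conc_mg_per_dl: float, mw_g_per_mol: float) -> float:
    """Convert a mass concentration in mg/dL to mol/cm^3.

    1 mg/dL = 1e-3 g per 100 cm^3; dividing by the molecular weight gives
    mol/cm^3.
    """
    if mw_g_per_mol <= 0:
        raise ValueError(f"molecular weight must be > 0, got {mw_g_per_mol}")
    if conc_mg_per_dl < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_mg_per_dl}")
    return conc_mg_per_dl * 1e-3 / (mw_g_per_mol * 100.0)


def micromolar_to_molar_volume(conc_umol_per_l: float) -> float:
    """Convert umol/L to mol/cm^3 (1 L = 1000 cm^3)."""
    if conc_umol_per_l < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_umol_per_l}")
    return conc_umol_per_l * 1e-6 / 1000.0


def microns_to_cm(length_um: float) -> float:
    return length_um * 1e-4


def hours_to_seconds(t_h: float) -> float:
    return t_h * 3600.0


def seconds_to_hours(t_s: float) -> float:
    return t_s / 3600.0
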