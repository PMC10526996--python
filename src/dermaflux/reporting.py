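"""Configuration loading, figure-table generation, and verification reports.

The tabular outputs regenerate the data behind the standard plots of the
step-response problem: spatial concentration profiles at representative
times for each boundary condition, and the family of normalized sensor
responses across the sensitivity spectrum.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dermaflux.domain import SensorKind, SensorSpec, SkinBarrier, alpha_bar as _alpha_bar
from dermaflux.fdm import solve_pde
from dermaflux.metrics import classify_sensor, integrated_intercept, robin_leading_timescale, timescale_report
from dermaflux.robin import robin_profile, robin_response, robin_response_curve
from dermaflux.series import (
    conc_profile_dirichlet,
    conc_profile_neumann,
    response_conc,
    response_curve,
    response_flux,
)

__all__ = [
    "FIGURE_TIMES",
    "figure_tables",
    "list_presets",
    "load_config",
    "run_config",
    "verify_deviations",
    "write_csv",
]

#: Representative dimensionless times for the spatial-profile tables, a
#: log-spaced subset of the range the profile plots customarily span.
FIGURE_TIMES = (0.01, 0.1, 1.0, 10.0)

CSV_FLOAT_FORMAT = "%.9g"


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV output: 9 significant digits, '.' decimal."""
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def figure_tables(which: int, n_x: int = 101, n_t: int = 301,
                  t_bar_max: float = 3.0) -> pd.DataFrame:
    """Tabulate the data behind one of the four standard figures.

    2 -> Neumann c_bar(x_bar) at the representative times;
    3 -> Dirichlet likewise; 4 -> Robin with alpha_bar = 1 likewise;
    5 -> normalized responses m_bar(t_bar) for the concentration, flux,
    and Robin (alpha_bar = 0.2, 1, 5) systems.
    """
    if which in (2, 3, 4):
        x = np.linspace(0.0, 1.0, n_x)
        frames = []
        for t in FIGURE_TIMES:
            if which == 2:
                c = conc_profile_neumann(x, t)
            elif which == 3:
                c = conc_profile_dirichlet(x, t)
            else:
                c = robin_profile(x, t, alpha_bar=1.0)
            frames.append(pd.DataFrame({"x_bar": x, "t_bar": t, "c_bar": c}))
        return pd.concat(frames, ignore_index=True)
    if which == 5:
        t = np.linspace(0.0, t_bar_max, n_t)
        return pd.DataFrame({
            "t_bar": t,
            "m_bar_conc": response_conc(t),
            "m_bar_robin_0.2": robin_response(t, 0.2),
            "m_bar_robin_1": robin_response(t, 1.0),
            "m_bar_robin_5": robin_response(t, 5.0),
            "m_bar_flux": response_flux(t),
        })
    raise ValueError(f"unknown figure id {which}; choose 2, 3, 4, or 5")


def verify_deviations(t_bar=None, x_step: float = 0.1,
                      robin_alpha_bars=(0.2, 1.0, 5.0),
                      nx: int = 601, dt_bar: float = 5e-5) -> pd.DataFrame:
    """Series-versus-finite-difference deviation table.

    For each boundary condition (and each Robin sensitivity) reports the
    maximum absolute difference between the analytic profile and the
    numerical oracle over the time/space verification grid.
    """
    if t_bar is None:
        t_bar = [0.01, 0.05, 0.1, 0.3, 1.0, 3.0]
    t_bar = np.asarray(t_bar, dtype=float)
    x_check = np.arange(0.0, 1.0 + 1e-12, x_step)

    rows = []
    cases = [("neumann", None), ("dirichlet", None)] + [("robin", ab) for ab in robin_alpha_bars]
    for boundary, ab in cases:
        field = solve_pde(boundary, t_bar, alpha_bar=ab, nx=nx, dt_bar=dt_bar)
        idx = np.rint(x_check * (nx - 1)).astype(int)
        num = field.c_bar[:, idx]
        tt, xx = np.meshgrid(t_bar, x_check, indexing="ij")
        if boundary == "neumann":
            ana = conc_profile_neumann(xx, tt)
        elif boundary == "dirichlet":
            ana = conc_profile_dirichlet(xx, tt)
        else:
            ana = robin_profile(xx, tt, alpha_bar=ab)
        rows.append({
            "boundary": boundary,
            "alpha_bar": ab if ab is not None else np.nan,
            "max_abs_deviation": float(np.max(np.abs(ana - num))),
        })
    return pd.DataFrame(rows)


def list_presets() -> list[str]:
    """Names of the bundled skin/sensor configuration presets."""
    pkg = resources.files("dermaflux") / "presets"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_config(source: str | Path) -> tuple[SkinBarrier, SensorSpec]:
    """Load a YAML/JSON config or a bundled preset name.

    Schema: ``skin: {D_cm2_per_s, L_cm, C0_mol_per_cm3}`` and
    ``sensor: {kind, alpha_cm_per_s}``.
    """
    source = str(source)
    if source in list_presets():
        text = (resources.files("dermaflux") / "presets" / f"{source}.yaml").read_text()
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(
                f"{source!r} is neither a config file nor a bundled preset {list_presets()}"
            )
        text = path.read_text()
    raw = json.loads(text) if source.endswith(".json") else yaml.safe_load(text)
    if not isinstance(raw, dict) or "skin" not in raw:
        raise ValueError("config must be a mapping with a 'skin' section")
    s = raw["skin"]
    try:
        skin = SkinBarrier(D=float(s["D_cm2_per_s"]), L=float(s["L_cm"]),
                           C0=float(s.get("C0_mol_per_cm3", 1.0)))
    except KeyError as exc:
        raise ValueError(f"skin section missing required key: {exc}") from exc
    sensor_raw = raw.get("sensor", {"kind": "concentration"})
    kind = SensorKind(sensor_raw.get("kind", "concentration"))
    alpha = sensor_raw.get("alpha_cm_per_s")
    sensor = SensorSpec(kind=kind, alpha=float(alpha) if alpha is not None else None)
    return skin, sensor


def run_config(source: str | Path, out_dir: str | Path,
               t_bar_max: float = 3.0, n_t: int = 301) -> dict:
    """Run the full pipeline for one configuration and write its artifacts.

    Writes the sampled response curve as CSV and a JSON report with the
    steady state, both timescale metrics, and (for Robin sensors) the
    classification; returns the report dict.
    """
    skin, sensor = load_config(source)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = np.linspace(0.0, t_bar_max, n_t)

    if sensor.kind is SensorKind.ROBIN:
        assert sensor.alpha is not None
        curve = robin_response_curve(t, skin, sensor.alpha)
        ab = _alpha_bar(sensor.alpha, skin)
        tau_s = robin_leading_timescale(ab, skin)
        icpt = integrated_intercept(SensorKind.ROBIN, alpha_bar=ab)
        classification = classify_sensor(ab)["label"]
    else:
        curve = response_curve(sensor.kind, t, skin)
        ts = timescale_report(skin)
        if sensor.kind is SensorKind.CONCENTRATION:
            tau_s, icpt = ts.tau_conc_s, ts.intercept_conc
            ab, classification = 0.0, "concentration-like"
        else:
            tau_s, icpt = ts.tau_flux_s, ts.intercept_flux
            ab, classification = float("inf"), "ideal-flux-like"

    write_csv(pd.DataFrame({"t_bar": curve.t_bar, "m_bar": curve.m_bar}),
              out / "response.csv")
    ts_all = timescale_report(skin)
    report = {
        "skin": {"D_cm2_per_s": skin.D, "L_cm": skin.L, "C0_mol_per_cm3": skin.C0,
                 "k_skin_cm_per_s": skin.permeability},
        "sensor": {"kind": sensor.kind.value, "alpha_cm_per_s": sensor.alpha,
                   "alpha_bar": ab if np.isfinite(ab) else None,
                   "classification": classification},
        "steady_state": {"value": curve.steady_state, "units": curve.units},
        "leading_timescale_s": tau_s,
        "leading_timescale_h": tau_s / 3600.0,
        "integrated_intercept_dimensionless": icpt,
        "timescales": ts_all.as_dict(),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, allow_nan=False, default=str)
    return report
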