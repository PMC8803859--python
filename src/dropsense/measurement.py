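"""Closed-system dynamics of bulk glucose and H2O2 in a hanging drop.

Once flow is stopped, the drop is a closed, evaporating compartment in
which four first-order processes shape the bulk concentrations: the
enzyme layer converts glucose to H2O2 (rate q_E), the spheroid consumes
glucose (q_S), the electrode consumes H2O2 by oxidation (q_e), and
evaporation at constant rate V_t upconcentrates everything through the
shrinking volume V(t) = V0 - V_t t:

    dc*_g/dt = -(q_E + q_S) c*_g + (c*_g / V) V_t
    dc*_h/dt =  q_E c*_g - q_e c*_h + (c*_h / V) V_t

Both have closed-form solutions; the measured current is
i(t) = F A m_h c*_h(t) in the no-flow steady-diffusion-layer regime, and
multiplying by the evaporation factor (1 - V_t t / V0) leaves a pure sum
of two exponentials — the object the Prony-style fit recovers.

A tight-tolerance ODE integration of the same system is provided purely
as a cross-check oracle for the closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .biosensor import HydrogelSensor
from .constants import PhysicalConstants

__all__ = [
    "DropGeometry",
    "MeasurementSetup",
    "CurrentTrace",
    "drop_volume",
    "height_to_volume_ratio",
    "glucose_bulk",
    "h2o2_bulk",
    "current",
    "evaporation_correct",
    "evaporation_factor",
    "ode_oracle",
]

#: Rates closer than this (min^-1) to the degenerate manifold
#: q_E + q_S = q_e are handled by the analytic L'Hopital limit.
DEGENERATE_RATE_TOL = 1e-9


@dataclass(frozen=True)
class DropGeometry:
    """Hanging-drop compartment geometry and evaporation record.

    Parameters
    ----------
    height_um : float
        Drop height h (um).
    aperture_mm : float
        Aperture diameter a (mm).
    n_drops : int
        Number of drops in the fluidic network, N.
    volume_uL : float
        Initial compartment volume V0 (uL).
    evap_rate_uL_min : float
        Evaporation rate V_t (uL min^-1), assumed constant within a
        measurement.
    """

    height_um: float = 600.0
    aperture_mm: float = 3.0
    n_drops: int = 8
    volume_uL: float = 6.5
    evap_rate_uL_min: float = 0.002

    def __post_init__(self) -> None:
        if min(self.height_um, self.aperture_mm, self.volume_uL) <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.evap_rate_uL_min < 0:
            raise ValueError("evaporation rate must be non-negative")
        if self.n_drops < 1:
            raise ValueError("need at least one drop")

    @property
    def horizon_min(self) -> float:
        """Time at which evaporation would exhaust the drop (min)."""
        if self.evap_rate_uL_min == 0:
            return math.inf
        return self.volume_uL / self.evap_rate_uL_min


@dataclass(frozen=True)
class MeasurementSetup:
    """Lumped parameters of one no-flow metabolism measurement.

    Rates are bulk first-order rates (min^-1); cg0/ch0 the bulk
    concentrations (uM) when flow stops; mh the H2O2 mass-transport
    coefficient (um min^-1) of the steady diffusion layer.
    """

    geometry: DropGeometry = DropGeometry()
    cg0: float = 150.0
    ch0: float = 0.0
    qE: float = 0.0016
    qS: float = 0.0
    qe: float = 0.0066
    mh: float = 400.0
    sensor: HydrogelSensor = field(default_factory=HydrogelSensor)
    constants: PhysicalConstants = PhysicalConstants()

    def __post_init__(self) -> None:
        if min(self.qE, self.qS, self.qe) < 0:
            raise ValueError("rates must be non-negative")
        if self.cg0 < 0 or self.ch0 < 0:
            raise ValueError("initial concentrations must be non-negative")
        if self.mh < 0:
            raise ValueError("mass transport coefficient must be non-negative")

    @property
    def famh(self) -> float:
        """Current per bulk H2O2 concentration, F A m_h (nA per uM)."""
        return self.constants.f_eff * self.sensor.area_mm2 * self.mh


@dataclass
class CurrentTrace:
    """A sampled amperometric trace with its drop/electrode metadata."""

    times: np.ndarray
    currents: np.ndarray
    drop_id: str = ""
    electrode: str = "GOx"  # "GOx" or "bare"
    spheroid_diameter_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.times.shape != self.currents.shape:
            raise ValueError("times and currents must have equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def _check_horizon(t, geometry: DropGeometry) -> np.ndarray:
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    if np.any(t_arr >= geometry.horizon_min):
        raise ValueError(
            f"time beyond the evaporation horizon V0/Vt = {geometry.horizon_min:g} min"
        )
    return t_arr


def drop_volume(t, geometry: DropGeometry) -> np.ndarray | float:
    """Drop volume V(t) = V0 - V_t t (uL), strictly positive within the horizon."""
    t_arr = _check_horizon(t, geometry)
    out = geometry.volume_uL - geometry.evap_rate_uL_min * t_arr
    return out if out.ndim else float(out)


def evaporation_factor(t, geometry: DropGeometry) -> np.ndarray | float:
    """The factor (1 - V_t t / V0) multiplying i(t) to undo upconcentration."""
    t_arr = _check_horizon(t, geometry)
    out = 1.0 - geometry.evap_rate_uL_min * t_arr / geometry.volume_uL
    return out if out.ndim else float(out)


def height_to_volume_ratio(geometry: DropGeometry) -> float:
    """Spherical-cap height sensitivity h/V = 8 / (pi N (a^2 + 4 h^2)), in um per uL.

    Used by the drop-height feedback to convert an imaged height change
    into the volume correction to apply across the N-drop network.
    """
    a_mm = geometry.aperture_mm
    h_mm = geometry.height_um * 1e-3
    ratio_per_mm3 = 8.0 / (math.pi * geometry.n_drops * (a_mm**2 + 4.0 * h_mm**2))  # mm/mm^3
    return ratio_per_mm3 * 1e3  # mm/uL -> um/uL


def glucose_bulk(t, setup: MeasurementSetup) -> np.ndarray | float:
    """Bulk glucose c*_g(t) = cg0 exp(-(q_E+q_S) t) / (1 - V_t t / V0) (uM)."""
    t_arr = _check_horizon(t, setup.geometry)
    fac = 1.0 - setup.geometry.evap_rate_uL_min * t_arr / setup.geometry.volume_uL
    out = setup.cg0 / fac * np.exp(-(setup.qE + setup.qS) * t_arr)
    return out if out.ndim else float(out)


def h2o2_bulk(t, setup: MeasurementSetup) -> np.ndarray | float:
    """Bulk H2O2 c*_h(t) (uM), closed form.

    c*_h(t) = [ch0 e^{-qe t}
               + cg0 qE/(qE+qS-qe) (e^{-qe t} - e^{-(qE+qS) t})] / (1 - Vt t/V0)

    On the degenerate manifold q_E + q_S = q_e the bracket's limit
    ch0 e^{-qe t} + cg0 qE t e^{-qe t} is used instead.
    """
    t_arr = _check_horizon(t, setup.geometry)
    fac = 1.0 - setup.geometry.evap_rate_uL_min * t_arr / setup.geometry.volume_uL
    qtot = setup.qE + setup.qS
    if abs(qtot - setup.qe) < DEGENERATE_RATE_TOL:
        bracket = (setup.ch0 + setup.cg0 * setup.qE * t_arr) * np.exp(-setup.qe * t_arr)
    else:
        amp = setup.cg0 * setup.qE / (qtot - setup.qe)
        bracket = setup.ch0 * np.exp(-setup.qe * t_arr) + amp * (
            np.exp(-setup.qe * t_arr) - np.exp(-qtot * t_arr)
        )
    out = bracket / fac
    return out if out.ndim else float(out)


def current(t, setup: MeasurementSetup) -> np.ndarray | float:
    """Measured current i(t) = F A m_h c*_h(t) (nA)."""
    ch = h2o2_bulk(t, setup)
    return setup.famh * ch


def evaporation_correct(trace: CurrentTrace, geometry: DropGeometry) -> CurrentTrace:
    """Multiply the trace by (1 - V_t t / V0), separating consumption from evaporation.

    The corrected series y(t) is an exact sum of two exponentials under
    the measurement model, making it the input to the exponential fit.
    """
    fac = evaporation_factor(trace.times, geometry)
    return CurrentTrace(
        times=trace.times.copy(),
        currents=trace.currents * fac,
        drop_id=trace.drop_id,
        electrode=trace.electrode,
        spheroid_diameter_um=trace.spheroid_diameter_um,
    )


def ode_oracle(
    setup: MeasurementSetup,
    t_grid: np.ndarray,
    rtol: float = 1e-11,
    atol: float = 1e-13,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the coupled bulk ODEs numerically (test oracle only).

    Returns (glucose uM, H2O2 uM) on ``t_grid``.  Exists solely to
    cross-validate the closed forms; the analysis pipeline never calls
    it.
    """
    t_grid = _check_horizon(t_grid, setup.geometry)
    V0 = setup.geometry.volume_uL
    Vt = setup.geometry.evap_rate_uL_min

    def rhs(t: float, y: np.ndarray) -> list[float]:
        cg, ch = y
        up = Vt / (V0 - Vt * t)
        return [
            -(setup.qE + setup.qS) * cg + cg * up,
            setup.qE * cg - setup.qe * ch + ch * up,
        ]

    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid[-1])),
        [setup.cg0, setup.ch0],
        t_eval=t_grid,
        method="DOP853",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE oracle failed: {sol.message}")
    return sol.y[0], sol.y[1]
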