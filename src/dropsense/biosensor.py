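"""Microscale model of the GOx-functionalized hydrogel electrode.

A platinum disk electrode is coated with a thin enzyme-loaded hydrogel of
thickness ``H``.  Glucose diffuses in from the bulk at ``x = H`` and is
converted to H2O2 by glucose oxidase with first-order rate ``v_g``; the
H2O2 diffuses to the electrode surface at ``x = 0`` where its oxidation
produces the measured current.  At steady state the glucose profile obeys

    D_g c_g'' - v_g c_g = 0,    c_g'(0) = 0,    c_g(H) = c*_g

whose solution is governed by a single dimensionless group, the biosensor
number ``B = H sqrt(v_g / D_g)`` (a second-Damkohler/Thiele-type modulus):
small ``B`` means the whole hydrogel converts glucose, large ``B`` means
only a surface layer does.  All the sensor's calibration observables
(slopes, average enzymatic rate) are closed forms in ``B``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import PhysicalConstants

__all__ = [
    "HydrogelSensor",
    "biosensor_number",
    "hydrogel_glucose_profile",
    "hydrogel_h2o2_profile",
    "h2o2_calibration_slope",
    "glucose_calibration_slope",
    "enzymatic_rate_qE",
    "qE_from_slope",
    "btilde_from_slope",
    "bulk_rate",
]


def _sech(x: float) -> float:
    """Numerically stable sech, safe for large argument."""
    ax = abs(x)
    if ax > 350.0:
        return 2.0 * math.exp(-ax)
    e = math.exp(-ax)
    return 2.0 * e / (1.0 + e * e)


def _one_minus_sech(x: float) -> float:
    """1 - sech(x) without cancellation for small x.

    Uses cosh(x) - 1 = 2 sinh^2(x/2), exact to machine precision for all
    x; falls back to 1 - sech for large x where cosh would overflow.
    """
    ax = abs(x)
    if ax > 350.0:
        return 1.0 - _sech(ax)
    s = math.sinh(ax / 2.0)
    return 2.0 * s * s / math.cosh(ax)


def _coth(x: float) -> float:
    if x == 0.0:
        raise ZeroDivisionError("coth(0) is undefined")
    if abs(x) > 20.0:
        return math.copysign(1.0, x)
    return 1.0 / math.tanh(x)


@dataclass(frozen=True)
class HydrogelSensor:
    """Geometry, diffusivities and enzymatic rate of one functionalized electrode.

    Parameters
    ----------
    area_mm2 : float
        Electrode surface area A (mm^2); default is a 0.4 mm-diameter disk.
    thickness_um : float
        Hydrogel layer thickness H (um).
    diff_glucose : float
        Glucose diffusivity D_g in the hydrogel (um^2 min^-1).
    diff_h2o2 : float
        H2O2 diffusivity D_h in the hydrogel (um^2 min^-1).
    rate_vg : float
        First-order enzymatic glucose conversion rate v_g (min^-1).

    Notes
    -----
    Default diffusivities are buffer values scaled by the hydrogel
    hindrance factors (glucose 0.062-0.086x, H2O2 0.25-0.40x of buffer);
    the defaults use mid-range factors and are ordinary config values.
    """

    area_mm2: float = math.pi * 0.2**2
    thickness_um: float = 5.0
    diff_glucose: float = 2800.0
    diff_h2o2: float = 28000.0
    rate_vg: float = 7.0

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0 or self.thickness_um <= 0:
            raise ValueError("area and thickness must be positive")
        if self.diff_glucose < 0 or self.diff_h2o2 < 0 or self.rate_vg < 0:
            raise ValueError("diffusivities and rate must be non-negative")
        if self.rate_vg > 0 and self.diff_glucose == 0:
            raise ValueError("zero glucose diffusivity with nonzero enzymatic rate")

    # Derived quantities as methods so a sensor object reads naturally.
    def biosensor_number(self) -> float:
        return biosensor_number(self)

    def glucose_slope(self, constants: PhysicalConstants = PhysicalConstants()) -> float:
        return glucose_calibration_slope(self, constants)

    def h2o2_slope(self, constants: PhysicalConstants = PhysicalConstants()) -> float:
        return h2o2_calibration_slope(self, constants)

    def enzymatic_rate(self) -> float:
        return enzymatic_rate_qE(self)

    @property
    def hydrogel_volume_uL(self) -> float:
        """Hydrogel volume A*H in uL (mm^2 * um * 1e-3)."""
        return self.area_mm2 * self.thickness_um * 1e-3


def biosensor_number(sensor: HydrogelSensor) -> float:
    """Dimensionless biosensor number B = H sqrt(v_g / D_g)."""
    if sensor.rate_vg == 0.0:
        return 0.0
    return sensor.thickness_um * math.sqrt(sensor.rate_vg / sensor.diff_glucose)


def hydrogel_glucose_profile(sensor: HydrogelSensor, bulk_cg: float, x) -> np.ndarray | float:
    """Steady-state glucose concentration c_g(x) in the hydrogel (uM).

    c_g(x) = c*_g cosh(x sqrt(v_g/D_g)) / cosh(B), with zero flux at the
    electrode (x = 0) and the bulk value at the hydrogel surface (x = H).
    """
    x_arr = np.asarray(x, dtype=float)
    H = sensor.thickness_um
    if np.any(x_arr < 0) or np.any(x_arr > H):
        raise ValueError(f"x must lie in [0, {H}] um")
    if sensor.rate_vg == 0.0:
        out = np.full_like(x_arr, float(bulk_cg))
        return out if out.ndim else float(out)
    kappa = math.sqrt(sensor.rate_vg / sensor.diff_glucose)
    btilde = H * kappa
    # cosh(kx)/cosh(B) = exp(kx - B) (1 + exp(-2kx)) / (1 + exp(-2B)),
    # stable for arbitrarily large B since kx <= B.
    kx = kappa * x_arr
    ratio = np.exp(kx - btilde) * (1.0 + np.exp(-2.0 * kx)) / (1.0 + math.exp(-2.0 * btilde))
    out = float(bulk_cg) * ratio
    return out if out.ndim else float(out)


def hydrogel_h2o2_profile(sensor: HydrogelSensor, bulk_cg: float, x) -> np.ndarray | float:
    """Steady-state H2O2 concentration c_h(x) in the hydrogel during glucose flow (uM).

    Solves D_h c_h'' + v_g c_g(x) = 0 with c_h(0) = c_h(H) = 0, the H2O2
    produced by the enzyme being consumed at the electrode and washed away
    at the surface.  Closed form (k = sqrt(v_g/D_g)):

        c_h(x) = c*_g (D_g/D_h) [ sech(B) - cosh(kx)/cosh(B)
                                  + (x/H)(1 - sech(B)) ]

    whose electrode-surface gradient reproduces the glucose calibration
    slope via i = F A D_h c_h'(0).
    """
    x_arr = np.asarray(x, dtype=float)
    H = sensor.thickness_um
    if np.any(x_arr < 0) or np.any(x_arr > H):
        raise ValueError(f"x must lie in [0, {H}] um")
    if sensor.rate_vg == 0.0:
        out = np.zeros_like(x_arr)
        return out if out.ndim else float(out)
    btilde = biosensor_number(sensor)
    cg = np.asarray(hydrogel_glucose_profile(sensor, 1.0, x_arr), dtype=float)
    term = (_sech(btilde) - cg) + (x_arr / H) * _one_minus_sech(btilde)
    out = float(bulk_cg) * (sensor.diff_glucose / sensor.diff_h2o2) * term
    return out if out.ndim else float(out)


def h2o2_calibration_slope(
    sensor: HydrogelSensor, constants: PhysicalConstants = PhysicalConstants()
) -> float:
    """H2O2 calibration slope F A D_h / H (nA per uM)."""
    return constants.f_eff * sensor.area_mm2 * sensor.diff_h2o2 / sensor.thickness_um


def glucose_calibration_slope(
    sensor: HydrogelSensor, constants: PhysicalConstants = PhysicalConstants()
) -> float:
    """Glucose calibration slope b = F A (D_g/H) (1 - sech B) (nA per uM).

    Monotonically increasing in B, saturating at F A D_g / H: thicker or
    more active hydrogels give diminishing sensitivity returns as glucose
    is depleted near the hydrogel surface.
    """
    btilde = biosensor_number(sensor)
    scale = constants.f_eff * sensor.area_mm2 * sensor.diff_glucose / sensor.thickness_um
    return scale * _one_minus_sech(btilde)


def enzymatic_rate_qE(sensor: HydrogelSensor) -> float:
    """Volume-averaged first-order enzymatic rate q_E = (sqrt(v_g D_g)/H) tanh(B) (min^-1).

    This is the hydrogel-volume average of v_g c_g(x)/c*_g; it satisfies
    0 <= q_E <= v_g, approaching v_g as B -> 0 (entire hydrogel active).
    """
    if sensor.rate_vg == 0.0:
        return 0.0
    btilde = biosensor_number(sensor)
    return (
        math.sqrt(sensor.rate_vg * sensor.diff_glucose)
        / sensor.thickness_um
        * math.tanh(btilde)
    )


def qE_from_slope(
    slope_b: float,
    btilde: float,
    area_mm2: float,
    thickness_um: float,
    constants: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Enzymatic rate from the calibration slope: q_E = b B coth(B/2) / (F A H).

    The identity tanh(B)/(1 - sech B) = coth(B/2) ties the measurable
    slope b to the average enzymatic rate without knowing v_g directly.
    At B -> 0 the finite limit q_E = 2 b / (F A H) is used.
    """
    if slope_b <= 0:
        raise ValueError("slope_b must be positive")
    if btilde < 0:
        raise ValueError("btilde must be non-negative")
    fah = constants.f_eff * area_mm2 * thickness_um
    if btilde < 1e-8:
        return 2.0 * slope_b / fah
    return slope_b * btilde * _coth(btilde / 2.0) / fah


def btilde_from_slope(
    slope_b: float,
    area_mm2: float,
    thickness_um: float,
    diff_glucose: float,
    constants: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Invert the glucose calibration slope for the biosensor number.

    The slope b = F A (D_g/H)(1 - sech B) increases strictly from 0 to
    the saturation bound F A D_g/H, so the inverse is unique; solved by
    bracketed root finding on B in [0, 1e3].
    """
    if slope_b <= 0:
        raise ValueError("slope_b must be positive")
    saturation = constants.f_eff * area_mm2 * diff_glucose / thickness_um
    if slope_b >= saturation:
        raise ValueError(
            f"slope {slope_b:g} at or above the saturation bound {saturation:g} "
            "nA/uM; no biosensor number reproduces it"
        )
    target = slope_b / saturation  # = 1 - sech(B), in (0, 1)
    root = brentq(lambda B: _one_minus_sech(B) - target, 0.0, 1e3, xtol=1e-14, rtol=8.9e-16)
    return float(root)


def bulk_rate(rate_per_hydrogel: float, sensor: HydrogelSensor, drop_volume_uL: float) -> float:
    """Convert a hydrogel-volume-average rate to a bulk drop rate (min^-1).

    The microscale q_E is an average over the hydrogel volume A*H; the
    closed-system drop equations need the rate at which the *drop's* bulk
    glucose is consumed, which is smaller by the volume ratio A*H/V
    (~1e-4 for a 5 um film on a 0.13 mm^2 disk in a ~7 uL drop).
    """
    if drop_volume_uL <= 0:
        raise ValueError("drop volume must be positive")
    return rate_per_hydrogel * sensor.hydrogel_volume_uL / drop_volume_uL
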