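"""Microscale model of glucose diffusion and consumption in a spheroid.

A spherical cell aggregate of radius ``R`` consumes glucose with
first-order kinetics ``v_S`` while glucose diffuses inward with effective
tissue diffusivity ``D_S``.  The steady-state radial profile obeys

    D_S (1/r^2) d/dr (r^2 dc_g/dr) - v_S c_g = 0,
    c_g'(0) = 0,  c_g(R) = c*_g

and is governed by the dimensionless spheroid number
``S = R sqrt(v_S / D_S)``: a small ``S`` means the whole spheroid
consumes ("consuming sphere"), a large ``S`` means only an outer shell
does ("consuming shell").  The effectiveness factor
``(3/S^2)(S coth S - 1)`` — the metabolism ratio — is the fraction of
the uniform-consumption rate actually achieved, i.e. the proportion of
cells participating in glucose metabolization.

The inverse problem — recovering ``S`` from a measured bulk consumption
rate ``q_S`` and the microscopically measured radius, given ``D_S`` — is
solved by bracketed root finding of the strictly increasing map
``S coth S - 1``.

The first-order assumption restricts validity to low glucose
(starvation-level, ~150 uM) conditions; Michaelis-Menten or zeroth-order
uptake is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SpheroidModel",
    "SpheroidObservation",
    "spheroid_number",
    "spheroid_glucose_profile",
    "spheroid_consumption_qS",
    "metabolism_ratio",
    "fit_spheroid_number",
]


def _coth(x: float) -> float:
    if abs(x) > 20.0:
        return math.copysign(1.0, x)
    return 1.0 / math.tanh(x)


@dataclass(frozen=True)
class SpheroidModel:
    """Radius, tissue diffusivity and cellular uptake rate of one spheroid.

    Parameters
    ----------
    radius_um : float
        Spheroid radius R (um), from wide-field microscopy.
    diff_tissue : float
        Effective glucose diffusivity D_S in tissue (um^2 min^-1).
    rate_vS : float
        First-order cellular consumption rate v_S (min^-1).
    """

    radius_um: float
    diff_tissue: float
    rate_vS: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")
        if self.diff_tissue <= 0:
            raise ValueError("tissue diffusivity must be positive")
        if self.rate_vS < 0:
            raise ValueError("consumption rate must be non-negative")

    def spheroid_number(self) -> float:
        return spheroid_number(self)

    def consumption_rate(self) -> float:
        return spheroid_consumption_qS(self)

    def metabolism_ratio(self) -> float:
        return metabolism_ratio(self.spheroid_number())


@dataclass(frozen=True)
class SpheroidObservation:
    """One measured spheroid: identifier, diameter and fitted bulk consumption."""

    drop_id: str
    diameter_um: float
    fitted_qS: float
    electrode_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if self.fitted_qS < 0:
            raise ValueError("fitted q_S must be non-negative")

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0


def spheroid_number(model: SpheroidModel) -> float:
    """Dimensionless spheroid number S = R sqrt(v_S / D_S)."""
    if model.rate_vS == 0.0:
        return 0.0
    return model.radius_um * math.sqrt(model.rate_vS / model.diff_tissue)


def spheroid_glucose_profile(model: SpheroidModel, bulk_cg: float, r) -> np.ndarray | float:
    """Steady-state radial glucose profile c_g(r) in the spheroid (uM).

    c_g(r) = c*_g (R/r) sinh(S r/R) / sinh(S), with the removable
    singularity at the centre evaluated by its series limit
    c_g(0) = c*_g S / sinh(S).
    """
    r_arr = np.asarray(r, dtype=float)
    R = model.radius_um
    if np.any(r_arr < 0) or np.any(r_arr > R):
        raise ValueError(f"r must lie in [0, {R}] um")
    stilde = spheroid_number(model)
    if stilde == 0.0:
        out = np.full_like(r_arr, float(bulk_cg))
        return out if out.ndim else float(out)
    u = stilde * r_arr / R
    out = np.empty_like(r_arr)
    small = u < 1e-4
    # sinh(u)/u -> 1 + u^2/6 for tiny u; elsewhere direct evaluation.
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(
            small,
            (1.0 + u * u / 6.0),
            np.sinh(u) / np.where(small, 1.0, u),
        )
    out = float(bulk_cg) * stilde / math.sinh(stilde) * out
    return out if out.ndim else float(out)


def spheroid_consumption_qS(model: SpheroidModel) -> float:
    """Volume-averaged consumption rate q_S = 3 (D_S/R^2)(S coth S - 1) (min^-1).

    Equals the volume average of v_S c_g(r)/c*_g; tends to v_S as S -> 0
    (fully participating spheroid) and satisfies 0 <= q_S <= v_S.
    """
    stilde = spheroid_number(model)
    scale = 3.0 * model.diff_tissue / model.radius_um**2
    return scale * _s_coth_s_minus_1(stilde)


def _s_coth_s_minus_1(s: float) -> float:
    """S coth S - 1, series-expanded near 0 to avoid cancellation.

    Direct evaluation loses ~|eps|/S^2 relative accuracy as S -> 0; the
    truncated series S^2/3 - S^4/45 + 2 S^6/945 is accurate to ~1e-11
    at the 1e-2 branch point.
    """
    if s < 1e-2:
        s2 = s * s
        return s2 / 3.0 - s2 * s2 / 45.0 + 2.0 * s2 * s2 * s2 / 945.0
    return s * _coth(s) - 1.0


def metabolism_ratio(stilde: float) -> float:
    """Effectiveness factor (3/S^2)(S coth S - 1), in (0, 1].

    The fraction of cells participating in glucose metabolization: 1 for
    a vanishing spheroid number (uniform consumption) and ~3/S for large
    S (only an outer shell consumes).
    """
    if stilde < 0:
        raise ValueError("spheroid number must be non-negative")
    if stilde < 1e-2:
        # series: 1 - S^2/15 + 2 S^4/315 - S^6/4725
        s2 = stilde * stilde
        return 1.0 - s2 / 15.0 + 2.0 * s2 * s2 / 315.0
    return 3.0 / stilde**2 * _s_coth_s_minus_1(stilde)


def fit_spheroid_number(
    obs: SpheroidObservation | float,
    diff_tissue: float,
    qS: Optional[float] = None,
) -> float:
    """Invert q_S = 3 (D_S/R^2)(S coth S - 1) for the spheroid number.

    Parameters
    ----------
    obs : SpheroidObservation or float
        Either an observation carrying diameter and fitted q_S, or the
        spheroid radius in um (then ``qS`` must be given).
    diff_tissue : float
        Effective tissue diffusivity D_S (um^2 min^-1).  Not printed by
        typical experiments; must be supplied and recorded.
    qS : float, optional
        Bulk consumption rate (min^-1) when ``obs`` is a bare radius.

    Returns
    -------
    float
        The unique S >= 0 with S coth S - 1 = q_S R^2 / (3 D_S).
    """
    if isinstance(obs, SpheroidObservation):
        radius, q = obs.radius_um, obs.fitted_qS
    else:
        if qS is None:
            raise TypeError("qS must be provided when obs is a radius")
        radius, q = float(obs), float(qS)
    if diff_tissue <= 0:
        raise ValueError("tissue diffusivity must be positive")
    rhs = q * radius**2 / (3.0 * diff_tissue)
    if rhs < 0:
        raise ValueError("negative consumption rate: no spheroid number exists")
    if rhs == 0.0:
        return 0.0
    if rhs < 1e-9:
        return math.sqrt(3.0 * rhs)  # series branch: S^2/3 = rhs
    # S coth S - 1 is strictly increasing, ~S for large S: bracket generously.
    hi = max(10.0, 2.0 * (rhs + 1.0))
    return float(brentq(lambda s: _s_coth_s_minus_1(s) - rhs, 1e-9, hi, xtol=1e-14, rtol=8.9e-16))
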