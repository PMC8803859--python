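"""Sensor calibration: staircase traces -> sensitivity, LoD, linearity, q_E.

A flow calibration perfuses a sequence of known glucose concentrations
(typically the 3-point staircase 0, 75, 150 uM) and records the current
plateau of each step.  The plateau means against the concentrations give
the sensitivity (slope b, nA per uM), the blank-step noise gives a
parametric limit of detection k * sd_blank / b, and the slope chains
through the biosensor closed forms into the biosensor number and the
average enzymatic rate q_E consumed by the rate extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .biosensor import btilde_from_slope, qE_from_slope
from .constants import PhysicalConstants
from .measurement import CurrentTrace

__all__ = [
    "CalibrationSchedule",
    "CalibrationResult",
    "CalibrationModel",
    "plateau_stats",
    "sensitivity_from_plateaus",
    "limit_of_detection",
    "qE_from_calibration",
    "linearity_deviation",
    "mean_sensitivity",
]

#: Default IUPAC-style parametric LoD factor (blank SD over slope).
DEFAULT_LOD_K = 3.3


@dataclass(frozen=True)
class CalibrationSchedule:
    """Ordered concentration steps of a flow calibration.

    Parameters
    ----------
    steps : sequence of (concentration uM, duration min)
        Perfusion steps in order; the classic staircase is
        ((0, 20), (75, 20), (150, 20)).
    mixing_tau : float
        First-order drop-exchange time constant (min) governing how fast
        the drop approaches each new target; used when synthesizing
        staircases, informative metadata when analysing real ones.
    """

    steps: tuple[tuple[float, float], ...] = ((0.0, 20.0), (75.0, 20.0), (150.0, 20.0))
    mixing_tau: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple((float(c), float(d)) for c, d in self.steps))
        for conc, dur in self.steps:
            if dur <= 0:
                raise ValueError("step durations must be positive")
            if conc < 0:
                raise ValueError("step concentrations must be non-negative")
        if self.mixing_tau < 0:
            raise ValueError("mixing_tau must be non-negative")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.steps])

    @property
    def durations(self) -> np.ndarray:
        return np.array([d for _, d in self.steps])

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    @property
    def edges(self) -> np.ndarray:
        """Step start times, plus the final end time."""
        return np.concatenate([[0.0], np.cumsum(self.durations)])


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted sensitivity line and derived figures of merit."""

    slope_b: float  # nA per uM
    intercept: float  # nA
    r_squared: float
    lod: float  # uM
    plateau_means: tuple[float, ...]
    plateau_sds: tuple[float, ...]
    concentrations: tuple[float, ...]
    lod_k_factor: float = DEFAULT_LOD_K

    def summary(self) -> str:
        lines = [
            "Flow calibration fit",
            "=" * 46,
            f"sensitivity b : {self.slope_b:.5g} nA/uM "
            f"({self.slope_b * 1e3:.3g} nA/mM)",
            f"intercept     : {self.intercept:.4g} nA",
            f"r^2           : {self.r_squared:.6f}",
            f"LoD (k={self.lod_k_factor:g})  : {self.lod:.3g} uM",
            "-" * 46,
            f"{'conc (uM)':>12}{'plateau (nA)':>16}{'sd (nA)':>12}",
        ]
        for c, m, s in zip(self.concentrations, self.plateau_means, self.plateau_sds):
            lines.append(f"{c:>12.1f}{m:>16.5f}{s:>12.2g}")
        return "\n".join(lines)


def plateau_stats(
    trace: CurrentTrace,
    schedule: CalibrationSchedule,
    tail_fraction: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD of the settled tail of each calibration step.

    Only the last ``tail_fraction`` of each step window is used, by which
    time the first-order drop exchange (tau of a few minutes against
    15-20 min steps) has decayed to a negligible residual.
    """
    if not (0.0 < tail_fraction <= 0.5):
        raise ValueError("tail_fraction must be in (0, 0.5]")
    t0 = trace.times[0]
    edges = schedule.edges + t0
    if trace.times[-1] < edges[-1] - 1e-9:
        raise ValueError("trace does not span the calibration schedule")
    means, sds = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        tail_lo = hi - tail_fraction * (hi - lo)
        mask = (trace.times >= tail_lo) & (trace.times < hi)
        if mask.sum() < 10:
            raise ValueError(
                f"step window [{lo:g}, {hi:g}) min has fewer than 10 tail samples"
            )
        seg = trace.currents[mask]
        means.append(float(np.mean(seg)))
        sds.append(float(np.std(seg, ddof=1)))
    return np.array(means), np.array(sds)


def sensitivity_from_plateaus(
    concentrations: Sequence[float],
    plateau_means: Sequence[float],
) -> tuple[float, float, float]:
    """OLS line through (concentration, plateau current): (slope, intercept, r^2)."""
    conc = np.asarray(concentrations, dtype=float)
    curr = np.asarray(plateau_means, dtype=float)
    if conc.size < 2 or np.ptp(conc) == 0:
        raise ValueError("need at least 2 distinct concentrations")
    res = stats.linregress(conc, curr)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def limit_of_detection(
    blank_sd: float, slope_b: float, k_factor: float = DEFAULT_LOD_K
) -> float:
    """Parametric LoD = k * sd(blank) / slope (uM)."""
    if slope_b <= 0:
        raise ValueError("slope must be positive for a functional sensor")
    if blank_sd < 0:
        raise ValueError("blank SD must be non-negative")
    return k_factor * blank_sd / slope_b


def qE_from_calibration(
    slope_b: float,
    area_mm2: float,
    thickness_um: float,
    diff_glucose: float,
    constants: PhysicalConstants = PhysicalConstants(),
) -> tuple[float, float]:
    """Chain the measured sensitivity into (biosensor number, q_E).

    Inverts the calibration-slope closed form for the biosensor number,
    then applies q_E = b B coth(B/2) / (F A H).  The returned q_E is the
    hydrogel-volume-average rate; scale by hydrogel/drop volume (see
    ``biosensor.bulk_rate``) before using it in the drop equations.
    """
    btilde = btilde_from_slope(slope_b, area_mm2, thickness_um, diff_glucose, constants)
    qE = qE_from_slope(slope_b, btilde, area_mm2, thickness_um, constants)
    return btilde, qE


def linearity_deviation(
    concentrations: Sequence[float],
    plateau_means: Sequence[float],
    fit_range_max: float,
) -> dict[float, float]:
    """Percent deviation from the low-range line at concentrations above the range.

    Fits the OLS line on points with concentration <= ``fit_range_max``
    and reports 100 * (line - measured)/line for each point above it —
    positive for a saturating (sub-linear) response.
    """
    conc = np.asarray(concentrations, dtype=float)
    curr = np.asarray(plateau_means, dtype=float)
    in_range = conc <= fit_range_max
    if in_range.sum() < 2:
        raise ValueError("need at least 2 points within the linear fit range")
    slope, intercept, _ = sensitivity_from_plateaus(conc[in_range], curr[in_range])
    out = {}
    for c, m in zip(conc[~in_range], curr[~in_range]):
        expected = slope * c + intercept
        out[float(c)] = float(100.0 * (expected - m) / expected)
    return out


class CalibrationModel:
    """Calibration staircase analysis in model/fit/results form.

    Parameters
    ----------
    trace : CurrentTrace
        The recorded staircase.
    schedule : CalibrationSchedule
        The perfused concentration steps.
    tail_fraction : float
        Fraction of each step treated as settled plateau.
    """

    def __init__(
        self,
        trace: CurrentTrace,
        schedule: CalibrationSchedule,
        tail_fraction: float = 0.25,
    ):
        self.trace = trace
        self.schedule = schedule
        self.tail_fraction = tail_fraction

    def fit(self, lod_k_factor: float = DEFAULT_LOD_K) -> CalibrationResult:
        means, sds = plateau_stats(self.trace, self.schedule, self.tail_fraction)
        conc = self.schedule.concentrations
        slope, intercept, r2 = sensitivity_from_plateaus(conc, means)
        blank_idx = int(np.argmin(conc))
        lod = limit_of_detection(sds[blank_idx], slope, lod_k_factor)
        return CalibrationResult(
            slope_b=slope,
            intercept=intercept,
            r_squared=r2,
            lod=lod,
            plateau_means=tuple(means),
            plateau_sds=tuple(sds),
            concentrations=tuple(conc),
            lod_k_factor=lod_k_factor,
        )


def mean_sensitivity(pre: CalibrationResult, post: Optional[CalibrationResult]) -> tuple[float, float]:
    """Average pre-/post-measurement sensitivities and report the drift.

    Returns (mean slope, relative drift (post-pre)/pre); drift is 0 when
    no post calibration is supplied.
    """
    if post is None:
        return pre.slope_b, 0.0
    mean = 0.5 * (pre.slope_b + post.slope_b)
    drift = (post.slope_b - pre.slope_b) / pre.slope_b
    return mean, drift
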