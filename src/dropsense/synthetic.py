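"""Synthetic trace generation: every input the analysis pipeline needs.

Real recordings from the hanging-drop rig are not redistributable, so
this module generates statistically faithful stand-ins: metabolism
decays from the closed-system measurement model, staircase calibrations
with first-order drop-exchange lag, traces replayed from the eight
published coefficient rows (including the complex-conjugate cases), a
multiplicative sensitivity drift across repeated measurements, and
additive Gaussian sensor noise at the instrument's ~1 pA level.  All
generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal

from .measurement import (
    CurrentTrace,
    DropGeometry,
    MeasurementSetup,
    current,
    evaporation_factor,
)

__all__ = [
    "NoiseModel",
    "Table1Fixture",
    "table1_fixtures",
    "simulate_metabolism_trace",
    "simulate_from_table1",
    "simulate_calibration_trace",
    "sensitivity_drift_series",
    "lowpass_filter",
]

#: Default additive current noise, nA (the readout's <1 pA noise floor).
DEFAULT_SIGMA_NA = 1e-3

#: Default per-measurement sensitivity decay reproducing the published
#: 9 -> 3.1 nA/mM decline over 10 successive measurements.
DEFAULT_DRIFT = (3.1 / 9.0) ** (1.0 / 9.0)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian sensor noise plus per-measurement sensitivity drift."""

    sigma_current: float = DEFAULT_SIGMA_NA
    seed: int = 0
    drift_per_measurement: float = DEFAULT_DRIFT

    def __post_init__(self) -> None:
        if self.sigma_current < 0:
            raise ValueError("noise SD must be non-negative")
        if not (0.0 < self.drift_per_measurement <= 1.0):
            raise ValueError("drift factor must be in (0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class Table1Fixture:
    """One published coefficient row: drop/electrode ids, spheroid size, (a, b, c, d)."""

    drop_id: int
    electrode_id: int
    spheroid_diameter_um: Optional[float]
    coef_a: complex
    rate_b: complex
    coef_c: complex
    rate_d: complex

    @property
    def is_conjugate(self) -> bool:
        return abs(self.coef_a.imag) > 0 or abs(self.rate_b.imag) > 0

    def structural_ok(self, tol: float = 1e-12) -> bool:
        """Conjugate rows must satisfy c = conj(a), d = conj(b); real rows have zero Im."""
        if self.is_conjugate:
            return (
                abs(self.coef_c - self.coef_a.conjugate()) < tol
                and abs(self.rate_d - self.rate_b.conjugate()) < tol
            )
        return (
            self.coef_a.imag == 0
            and self.rate_b.imag == 0
            and self.coef_c.imag == 0
            and self.rate_d.imag == 0
        )


# The eight published fitting-parameter rows: (drop, electrode, diameter,
# a, b, c, d).  Conjugate rows (drops 1-4, 8) satisfy c = conj(a),
# d = conj(b); rows 5-7 are purely real.
_TABLE1_ROWS = (
    (1, 2, None, 0.2617 + 0.4076j, -0.0015 - 0.0099j, 0.2617 - 0.4076j, -0.0015 + 0.0099j),
    (2, 17, 285.0, 0.4145 + 0.7545j, -0.0115 - 0.0073j, 0.4145 - 0.7545j, -0.0115 + 0.0073j),
    (3, 4, 286.0, 0.2841 + 1.2274j, -0.0142 - 0.0044j, 0.2841 - 1.2274j, -0.0142 + 0.0044j),
    (4, 15, 286.0, 0.2863 + 0.5251j, -0.0110 - 0.0088j, 0.2863 - 0.5251j, -0.0110 + 0.0088j),
    (5, 6, 452.0, 0.5481 + 0.0j, -0.0066 + 0.0j, -0.0339 + 0.0j, -0.0618 + 0.0j),
    (6, 13, 453.0, 0.6037 + 0.0j, -0.0070 + 0.0j, -0.0762 + 0.0j, -0.0497 + 0.0j),
    (7, 9, 453.0, 0.6107 + 0.0j, -0.0071 + 0.0j, -0.0608 + 0.0j, -0.0577 + 0.0j),
    (8, 10, None, 0.3083 + 0.4383j, -0.0016 - 0.0110j, 0.3083 - 0.4383j, -0.0016 + 0.0110j),
)


def table1_fixtures() -> list[Table1Fixture]:
    """The eight published coefficient rows as fixtures, verbatim."""
    return [Table1Fixture(*row) for row in _TABLE1_ROWS]


def _uniform_grid(duration: float, dt: float) -> np.ndarray:
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n = int(math.floor(duration / dt)) + 1
    return np.arange(n) * dt


def simulate_metabolism_trace(
    setup: MeasurementSetup,
    duration: float = 300.0,
    dt: float = 0.1,
    noise: NoiseModel = NoiseModel(),
    drop_id: str = "",
    spheroid_diameter_um: Optional[float] = None,
) -> CurrentTrace:
    """Sample the closed-form current on a uniform grid and add seeded noise."""
    times = _uniform_grid(duration, dt)
    if times[-1] >= setup.geometry.horizon_min:
        raise ValueError("duration exceeds the evaporation horizon")
    mean = np.asarray(current(times, setup), dtype=float)
    noisy = mean + noise.rng().normal(0.0, noise.sigma_current, size=times.size)
    return CurrentTrace(
        times=times,
        currents=noisy,
        drop_id=drop_id,
        electrode="GOx",
        spheroid_diameter_um=spheroid_diameter_um,
    )


def simulate_from_table1(
    fixture: Table1Fixture,
    geometry: DropGeometry = DropGeometry(),
    duration: float = 300.0,
    dt: float = 0.1,
    noise: NoiseModel = NoiseModel(sigma_current=0.0),
) -> CurrentTrace:
    """Replay a published coefficient row as a raw current trace.

    Builds the corrected signal y(t) = Re(a e^{bt} + c e^{dt}) and
    divides by the evaporation factor so the result looks like a raw
    recording i(t) that the pipeline must correct and fit back.
    """
    times = _uniform_grid(duration, dt)
    if times[-1] >= geometry.horizon_min:
        raise ValueError("duration exceeds the evaporation horizon")
    tc = times.astype(complex)
    y = np.real(
        fixture.coef_a * np.exp(fixture.rate_b * tc)
        + fixture.coef_c * np.exp(fixture.rate_d * tc)
    )
    i = y / np.asarray(evaporation_factor(times, geometry), dtype=float)
    if noise.sigma_current > 0:
        i = i + noise.rng().normal(0.0, noise.sigma_current, size=times.size)
    return CurrentTrace(
        times=times,
        currents=i,
        drop_id=f"drop{fixture.drop_id}",
        electrode="GOx",
        spheroid_diameter_um=fixture.spheroid_diameter_um,
    )


def simulate_calibration_trace(
    schedule,
    sensitivity: float,
    noise: NoiseModel = NoiseModel(),
    dt: float = 0.1,
    drop_id: str = "",
) -> CurrentTrace:
    """Synthesize a staircase calibration with first-order mixing lag.

    Within each step the current relaxes exponentially (time constant
    ``schedule.mixing_tau``) from its value at the step edge toward the
    asymptote sensitivity * concentration; ``mixing_tau = 0`` gives an
    ideal staircase.
    """
    edges = schedule.edges
    times = _uniform_grid(float(edges[-1]), dt)
    mean = np.empty_like(times)
    level = sensitivity * schedule.concentrations[0] if schedule.mixing_tau == 0 else 0.0
    tau = schedule.mixing_tau
    for (conc, _), lo, hi in zip(schedule.steps, edges[:-1], edges[1:]):
        target = sensitivity * conc
        mask = (times >= lo) & (times <= hi) if hi == edges[-1] else (times >= lo) & (times < hi)
        if tau == 0:
            mean[mask] = target
            level = target
        else:
            seg = target + (level - target) * np.exp(-(times[mask] - lo) / tau)
            mean[mask] = seg
            level = target + (level - target) * math.exp(-(hi - lo) / tau)
    noisy = mean + noise.rng().normal(0.0, noise.sigma_current, size=times.size)
    return CurrentTrace(times=times, currents=noisy, drop_id=drop_id, electrode="GOx")


def sensitivity_drift_series(
    initial_sensitivity: float,
    n_measurements: int,
    drift_per_measurement: float = DEFAULT_DRIFT,
) -> np.ndarray:
    """Sensitivity of each successive measurement under multiplicative decay.

    With the default factor, measurement 10 of a 9 nA/mM sensor sits at
    3.1 nA/mM, emulating enzyme deactivation across reuse.
    """
    if n_measurements < 1:
        raise ValueError("need at least one measurement")
    return initial_sensitivity * drift_per_measurement ** np.arange(n_measurements)


def lowpass_filter(
    trace: CurrentTrace,
    window_order: int = 1025,
    cutoff_hz: float = 0.05,
    sample_rate_hz: Optional[float] = None,
) -> CurrentTrace:
    """Zero-phase FIR low-pass with a Blackman window.

    Mirrors the instrument-side cleanup of raw potentiostat data.  The
    FIR taps have exactly unit DC gain, and forward-backward application
    cancels the phase delay.  The cutoff must lie below the Nyquist
    frequency; super-Nyquist requests are refused rather than silently
    aliased.
    """
    if sample_rate_hz is None:
        dt_min = float(np.mean(np.diff(trace.times)))
        sample_rate_hz = 1.0 / (dt_min * 60.0)
    if window_order % 2 == 0:
        raise ValueError("window_order must be odd")
    if window_order >= trace.times.size:
        raise ValueError("window_order must be smaller than the trace length")
    if not (0.0 < cutoff_hz < sample_rate_hz / 2.0):
        raise ValueError(
            f"cutoff {cutoff_hz:g} Hz outside (0, Nyquist={sample_rate_hz / 2:g} Hz)"
        )
    taps = signal.firwin(window_order, cutoff_hz, window="blackman", fs=sample_rate_hz)
    taps = taps / taps.sum()  # pin DC gain to exactly 1
    filtered = signal.filtfilt(taps, [1.0], trace.currents)
    return CurrentTrace(
        times=trace.times.copy(),
        currents=filtered,
        drop_id=trace.drop_id,
        electrode=trace.electrode,
        spheroid_diameter_um=trace.spheroid_diameter_um,
    )
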