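"""End-to-end analysis: traces in, per-drop consumption and spheroid numbers out.

The chain per drop: calibrate (sensitivity -> biosensor number -> q_E,
rescaled from hydrogel to bulk), evaporation-correct the metabolism
trace, fit the two-exponential model, map coefficients to rates
(q_e, q_E + q_S, m_h, c*_h0), invert the consumption rate for the
spheroid number S, and report the metabolism ratio and the
centre-to-surface glucose ratio.  Drops are processed independently —
cross-drop diffusion is a documented model neglect, not a term.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .biosensor import HydrogelSensor, bulk_rate
from .calibration import CalibrationModel, CalibrationSchedule, mean_sensitivity, qE_from_calibration
from .constants import PhysicalConstants
from .expfit import ExpFitResult, ExtractedRates, TwoExponentialModel
from .measurement import CurrentTrace, DropGeometry
from .spheroid import SpheroidModel, fit_spheroid_number, metabolism_ratio, spheroid_glucose_profile

logger = logging.getLogger("dropsense")

__all__ = ["AnalysisConfig", "DropResult", "AnalysisReport", "run_analysis", "reconstruct_glucose"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the pipeline needs beyond the traces themselves.

    ``diff_tissue`` (D_S, um^2 min^-1) has no consensus literature value
    for spheroids and directly scales every fitted spheroid number; it
    is therefore a required, explicitly recorded input.
    """

    sensor: HydrogelSensor = field(default_factory=HydrogelSensor)
    geometry: DropGeometry = field(default_factory=DropGeometry)
    constants: PhysicalConstants = PhysicalConstants()
    schedule: CalibrationSchedule = field(default_factory=CalibrationSchedule)
    cg0: float = 150.0
    diff_tissue: float = 82.0
    tail_fraction: float = 0.25

    def to_dict(self) -> dict:
        return {
            "sensor": {
                "area_mm2": self.sensor.area_mm2,
                "thickness_um": self.sensor.thickness_um,
                "Dg_um2_per_min": self.sensor.diff_glucose,
                "Dh_um2_per_min": self.sensor.diff_h2o2,
                "vg_per_min": self.sensor.rate_vg,
            },
            "geometry": {
                "height_um": self.geometry.height_um,
                "aperture_mm": self.geometry.aperture_mm,
                "n_drops": self.geometry.n_drops,
                "V0_uL": self.geometry.volume_uL,
                "Vt_uL_per_min": self.geometry.evap_rate_uL_min,
            },
            "faraday": self.constants.faraday,
            "n_electrons": self.constants.n_electrons,
            "cg0_uM": self.cg0,
            "DS_um2_per_min": self.diff_tissue,
            "tail_fraction": self.tail_fraction,
        }


@dataclass
class DropResult:
    """Per-drop analysis output."""

    drop_id: str
    solution_class: str
    fit: ExpFitResult
    rates: ExtractedRates
    qE_bulk: float
    btilde: float
    sensitivity: float
    sensitivity_drift: float
    spheroid_diameter_um: Optional[float] = None
    stilde: Optional[float] = None
    metabolism_ratio: Optional[float] = None
    center_surface_ratio: Optional[float] = None
    skipped_reason: Optional[str] = None


@dataclass
class AnalysisReport:
    """Assembled per-drop table plus provenance (config hash, version)."""

    drops: list[DropResult]
    config: AnalysisConfig
    version: str = __version__

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.drops:
            rows.append(
                {
                    "drop_id": d.drop_id,
                    "solution_class": d.solution_class,
                    "a_re_nA": float(np.real(d.fit.coef_a)),
                    "a_im_nA": float(np.imag(d.fit.coef_a)),
                    "b_re_per_min": float(np.real(d.fit.rate_b)),
                    "b_im_per_min": float(np.imag(d.fit.rate_b)),
                    "c_re_nA": float(np.real(d.fit.coef_c)),
                    "c_im_nA": float(np.imag(d.fit.coef_c)),
                    "d_re_per_min": float(np.real(d.fit.rate_d)),
                    "d_im_per_min": float(np.imag(d.fit.rate_d)),
                    "qe_per_min": d.rates.qe,
                    "qEqS_per_min": d.rates.qEqS_sum,
                    "qS_per_min": d.rates.qS,
                    "mh_um_per_min": d.rates.mh,
                    "ch0_uM": d.rates.ch0,
                    "qE_bulk_per_min": d.qE_bulk,
                    "btilde": d.btilde,
                    "sensitivity_nA_per_uM": d.sensitivity,
                    "sensitivity_drift": d.sensitivity_drift,
                    "spheroid_diameter_um": d.spheroid_diameter_um,
                    "Stilde": d.stilde,
                    "metabolism_ratio": d.metabolism_ratio,
                    "center_surface_glucose_ratio": d.center_surface_ratio,
                    "residual_rms_nA": d.fit.residual_rms,
                    "skipped_reason": d.skipped_reason,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        doc = {
            "version": self.version,
            "config": self.config.to_dict(),
            "config_hash": self.config_hash,
            "drops": [
                {**row, "fit": d.fit.to_dict()}
                for d, row in zip(
                    self.drops, self.to_frame().replace({np.nan: None}).to_dict("records")
                )
            ],
        }
        return json.dumps(doc, indent=2)

    def summary(self) -> str:
        df = self.to_frame()
        cols = [
            "drop_id", "solution_class", "qe_per_min", "qEqS_per_min",
            "qS_per_min", "Stilde", "metabolism_ratio",
        ]
        lines = [
            f"dropsense analysis report (v{self.version}, config {self.config_hash})",
            df[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def _analyse_drop(
    trace: CurrentTrace,
    calibrations: Sequence[CurrentTrace],
    config: AnalysisConfig,
) -> DropResult:
    cal_results = [
        CalibrationModel(c, config.schedule, config.tail_fraction).fit()
        for c in calibrations
    ]
    slope, drift = mean_sensitivity(
        cal_results[0], cal_results[1] if len(cal_results) > 1 else None
    )
    btilde, qE_gel = qE_from_calibration(
        slope,
        config.sensor.area_mm2,
        config.sensor.thickness_um,
        config.sensor.diff_glucose,
        config.constants,
    )
    qE_bulk = bulk_rate(qE_gel, config.sensor, config.geometry.volume_uL)

    model = TwoExponentialModel.from_trace(trace, config.geometry)
    res = model.fit()
    rates = res.extract_rates(
        qE=qE_bulk,
        cg0=config.cg0,
        sensor_area_mm2=config.sensor.area_mm2,
        constants=config.constants,
    )

    result = DropResult(
        drop_id=trace.drop_id,
        solution_class=res.solution_class,
        fit=res.result,
        rates=rates,
        qE_bulk=qE_bulk,
        btilde=btilde,
        sensitivity=slope,
        sensitivity_drift=drift,
        spheroid_diameter_um=trace.spheroid_diameter_um,
    )
    if trace.spheroid_diameter_um is not None and rates.qS > 0:
        radius = trace.spheroid_diameter_um / 2.0
        stilde = fit_spheroid_number(radius, config.diff_tissue, qS=rates.qS)
        result.stilde = stilde
        result.metabolism_ratio = metabolism_ratio(stilde)
        # centre depletion c(0)/c* = S / sinh S
        result.center_surface_ratio = (
            1.0 if stilde == 0 else stilde / math.sinh(stilde)
        )
    return result


def run_analysis(
    traces: Sequence[CurrentTrace],
    calibrations: dict[str, Sequence[CurrentTrace]],
    config: AnalysisConfig,
) -> AnalysisReport:
    """Analyse a set of metabolism traces with their per-drop calibrations.

    Parameters
    ----------
    traces : sequence of CurrentTrace
        One no-flow metabolism trace per drop.
    calibrations : mapping drop_id -> sequence of CurrentTrace
        One or two (pre/post) staircase calibration traces per drop.
        Drops with no calibration are skipped with a logged reason.
    config : AnalysisConfig

    Returns
    -------
    AnalysisReport
    """
    drops: list[DropResult] = []
    for trace in traces:
        cals = calibrations.get(trace.drop_id, ())
        if not cals:
            logger.warning("drop %s skipped: no calibration trace", trace.drop_id)
            drops.append(
                DropResult(
                    drop_id=trace.drop_id,
                    solution_class="",
                    fit=ExpFitResult(0, 0, 0, 0, "degenerate-single"),
                    rates=ExtractedRates(*(math.nan,) * 6),
                    qE_bulk=math.nan,
                    btilde=math.nan,
                    sensitivity=math.nan,
                    sensitivity_drift=math.nan,
                    spheroid_diameter_um=trace.spheroid_diameter_um,
                    skipped_reason="no calibration",
                )
            )
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                drops.append(_analyse_drop(trace, cals, config))
            logger.info("drop %s analysed", trace.drop_id)
        except (ValueError, RuntimeError) as exc:
            logger.warning("drop %s flagged: %s", trace.drop_id, exc)
            drops.append(
                DropResult(
                    drop_id=trace.drop_id,
                    solution_class="",
                    fit=ExpFitResult(0, 0, 0, 0, "degenerate-single"),
                    rates=ExtractedRates(*(math.nan,) * 6),
                    qE_bulk=math.nan,
                    btilde=math.nan,
                    sensitivity=math.nan,
                    sensitivity_drift=math.nan,
                    spheroid_diameter_um=trace.spheroid_diameter_um,
                    skipped_reason=str(exc),
                )
            )
    return AnalysisReport(drops=drops, config=config)


def reconstruct_glucose(
    rates: ExtractedRates,
    geometry: DropGeometry,
    cg0: float,
    times,
) -> np.ndarray:
    """Bulk glucose time course implied by the fitted rates.

    Evaluates c*_g(t) = cg0 exp(-(q_E + q_S) t) / (1 - V_t t/V0) with the
    fitted total consumption and the experimental evaporation record;
    instants beyond the evaporation horizon are truncated with a warning.
    """
    t = np.asarray(times, dtype=float)
    horizon = geometry.horizon_min
    if np.any(t >= horizon):
        warnings.warn("times beyond the evaporation horizon were truncated", stacklevel=2)
        t = t[t < horizon]
    fac = 1.0 - geometry.evap_rate_uL_min * t / geometry.volume_uL
    return cg0 / fac * np.exp(-rates.qEqS_sum * t)


def radial_glucose_table(
    stilde: float, diameter_um: float, cg0: float, n: int = 200
) -> pd.DataFrame:
    """Initial radial glucose distribution for a fitted spheroid number."""
    radius = diameter_um / 2.0
    # any (v_S, D_S) pair realising this S gives the same normalized profile
    model = SpheroidModel(radius_um=radius, diff_tissue=1.0, rate_vS=(stilde / radius) ** 2)
    r = np.linspace(0.0, radius, n)
    return pd.DataFrame(
        {
            "r_um": r,
            "r_over_R": r / radius,
            "cg_uM": np.asarray(spheroid_glucose_profile(model, cg0, r)),
        }
    )
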