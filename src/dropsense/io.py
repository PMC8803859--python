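"""Readers and writers for the pipeline's plain-text interchange formats.

Traces travel as two-column CSV (time_min, current_nA) with a JSON
sidecar for metadata; calibration schedules as YAML; fit results and
analysis reports as JSON (complex numbers as [re, im] pairs).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .calibration import CalibrationSchedule
from .measurement import CurrentTrace, DropGeometry

__all__ = [
    "write_trace",
    "read_trace",
    "read_schedule",
    "write_schedule",
    "load_config",
]


def write_trace(trace: CurrentTrace, csv_path: str | Path, sidecar: Optional[dict] = None) -> None:
    """Write a trace as CSV plus a JSON metadata sidecar (<name>.json)."""
    csv_path = Path(csv_path)
    pd.DataFrame({"time_min": trace.times, "current_nA": trace.currents}).to_csv(
        csv_path, index=False
    )
    meta = {
        "drop_id": trace.drop_id,
        "electrode": trace.electrode,
        "spheroid_diameter_um": trace.spheroid_diameter_um,
    }
    if sidecar:
        meta.update(sidecar)
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_trace(csv_path: str | Path) -> tuple[CurrentTrace, dict]:
    """Read a trace CSV and its JSON sidecar (if present)."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    if not {"time_min", "current_nA"} <= set(df.columns):
        raise ValueError(f"{csv_path}: expected columns time_min, current_nA")
    meta_path = csv_path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    trace = CurrentTrace(
        times=df["time_min"].to_numpy(),
        currents=df["current_nA"].to_numpy(),
        drop_id=str(meta.get("drop_id", "")),
        electrode=str(meta.get("electrode", "GOx")),
        spheroid_diameter_um=meta.get("spheroid_diameter_um"),
    )
    return trace, meta


def write_schedule(schedule: CalibrationSchedule, path: str | Path) -> None:
    doc = {
        "steps": [{"conc_uM": c, "duration_min": d} for c, d in schedule.steps],
        "mixing_tau_min": schedule.mixing_tau,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_schedule(path: str | Path) -> CalibrationSchedule:
    doc = yaml.safe_load(Path(path).read_text())
    steps = tuple((s["conc_uM"], s["duration_min"]) for s in doc["steps"])
    return CalibrationSchedule(steps=steps, mixing_tau=doc.get("mixing_tau_min", 0.0))


def load_config(path: str | Path) -> dict:
    """Load the single YAML pipeline config."""
    return yaml.safe_load(Path(path).read_text())


def geometry_from_config(cfg: dict) -> DropGeometry:
    return DropGeometry(
        height_um=cfg.get("height_um", 600.0),
        aperture_mm=cfg.get("aperture_mm", 3.0),
        n_drops=cfg.get("n_drops", 8),
        volume_uL=cfg.get("V0_uL", 6.5),
        evap_rate_uL_min=cfg.get("Vt_uL_per_min", 0.002),
    )
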