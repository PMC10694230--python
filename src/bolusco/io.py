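"""Plain-text round-tripping of curves, cohorts and model specs.

CSV dialect everywhere: comma-separated, ``.`` decimal, UTF-8, mandatory
header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anthropometry import PatientProfile
from .compartment import Compartment, CompartmentModelSpec, SimulatedCurve
from .errors import ValidationError
from .estimation import TimeDensityCurve
from .synthetic import SyntheticSubject

__all__ = [
    "read_tdc_csv", "write_tdc_csv", "write_simulated_curve_csv",
    "read_cohort_csv", "write_cohort_csv",
    "model_spec_to_dict", "model_spec_from_dict",
    "write_model_spec_yaml", "read_model_spec_yaml",
]

_COHORT_COLUMNS = ["id", "height_cm", "weight_kg", "sex", "pulse_bpm"]
_SEX_CODE = {"male": "M", "female": "F"}


def read_tdc_csv(path: str | Path, scan_delay_s: float | None = None,
                 baseline_hu: float | None = None,
                 complete_flag: str | None = None) -> TimeDensityCurve:
    """Read a ``time_s,hu`` table.

    ``scan_delay_s`` defaults to the first sample time; ``complete_flag``
    defaults to ``clipped_start`` when that time is positive, else
    ``complete``.
    """
    df = pd.read_csv(path)
    missing = {"time_s", "hu"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    times = df["time_s"].to_numpy(dtype=float)
    if scan_delay_s is None:
        scan_delay_s = float(times[0]) if times.size else 0.0
    if complete_flag is None:
        complete_flag = "clipped_start" if scan_delay_s > 0 else "complete"
    return TimeDensityCurve(times=times, hu=df["hu"].to_numpy(dtype=float),
                            scan_delay_s=scan_delay_s, baseline_hu=baseline_hu,
                            complete_flag=complete_flag)


def write_tdc_csv(tdc: TimeDensityCurve, path: str | Path) -> None:
    pd.DataFrame({"time_s": tdc.times, "hu": tdc.hu}).to_csv(
        path, index=False, float_format="%.6g")


def write_simulated_curve_csv(curve: SimulatedCurve, path: str | Path) -> None:
    pd.DataFrame({"time_s": curve.times,
                  "conc_mgI_per_ml": curve.concentration_mg_ml,
                  "hu": curve.hu}).to_csv(path, index=False,
                                          float_format="%.8g")


def read_cohort_csv(path: str | Path) -> list[PatientProfile]:
    df = pd.read_csv(path)
    missing = set(_COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [PatientProfile(height_cm=row.height_cm, weight_kg=row.weight_kg,
                           sex=str(row.sex), pulse_bpm=row.pulse_bpm,
                           id=str(row.id))
            for row in df.itertuples(index=False)]


def write_cohort_csv(subjects: list[SyntheticSubject], path: str | Path) -> None:
    """Write the cohort table; synthetic cohorts add the true CO column."""
    rows = [{"id": s.profile.id, "height_cm": s.profile.height_cm,
             "weight_kg": s.profile.weight_kg,
             "sex": _SEX_CODE[s.profile.sex],
             "pulse_bpm": s.profile.pulse_bpm,
             "co_true_l_min": s.co_true_l_min} for s in subjects]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def model_spec_to_dict(model: CompartmentModelSpec) -> dict:
    return {
        "total_blood_volume_l": model.total_blood_volume_l,
        "cardiac_output_l_min": model.cardiac_output_l_min,
        "pulse_bpm": model.pulse_bpm,
        "injection_compartment": model.injection_compartment,
        "observation_compartment": model.observation_compartment,
        "compartments": [
            {"name": c.name, "kind": c.kind, "volume_ml": c.volume_ml,
             "outflows_ml_s": dict(c.outflows_ml_s)}
            for c in model.compartments],
    }


def model_spec_from_dict(doc: dict) -> CompartmentModelSpec:
    comps = tuple(Compartment(name=c["name"], kind=c["kind"],
                              volume_ml=c["volume_ml"],
                              outflows_ml_s=dict(c["outflows_ml_s"]))
                  for c in doc["compartments"])
    return CompartmentModelSpec(
        compartments=comps,
        injection_compartment=doc["injection_compartment"],
        observation_compartment=doc["observation_compartment"],
        total_blood_volume_l=doc["total_blood_volume_l"],
        cardiac_output_l_min=doc["cardiac_output_l_min"],
        pulse_bpm=doc["pulse_bpm"])


def write_model_spec_yaml(model: CompartmentModelSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(model_spec_to_dict(model),
                                         sort_keys=False))


def read_model_spec_yaml(path: str | Path) -> CompartmentModelSpec:
    return model_spec_from_dict(yaml.safe_load(Path(path).read_text()))
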