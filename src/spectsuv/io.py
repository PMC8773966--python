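"""Table, volume and report I/O.

Formats: NIfTI-1 for 3-D volumes (float32, spacing from the header,
0-based voxel indices), CSV (comma, UTF-8, header, "." decimal) for patient
and lesion tables, YAML for patient records and configuration, JSON for the
analysis report.  Timestamps are ISO-8601 to the minute
("YYYY-MM-DDThh:mm").
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .quantification import ActivityVolume, PatientRecord, Sex, SUVVolume

__all__ = [
    "read_activity_volume",
    "write_volume",
    "read_patients_csv",
    "write_patients_csv",
    "read_patients_yaml",
    "read_lesion_table",
    "write_lesion_table",
    "load_config",
]

_TIME_FMT = "%Y-%m-%dT%H:%M"

LESION_COLUMNS = ["patient_id", "lesion_id", "category", "region",
                  "suv_max", "seed_i", "seed_j", "seed_k"]

PATIENT_COLUMNS = ["patient_id", "sex", "weight_kg", "height_cm",
                   "pre_injection_activity_mbq",
                   "post_injection_activity_mbq", "measured_time",
                   "administered_time", "post_injection_time", "scan_time",
                   "age_years"]


def read_activity_volume(path: str | Path) -> ActivityVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return ActivityVolume(grid=np.asarray(img.get_fdata(), dtype=np.float32),
                          voxel_spacing_mm=spacing, origin_mm=origin)


def write_volume(vol: ActivityVolume | SUVVolume, path: str | Path) -> None:
    affine = np.diag(list(vol.voxel_spacing_mm) + [1.0])
    affine[:3, 3] = vol.origin_mm
    img = nib.Nifti1Image(np.asarray(vol.grid, dtype=np.float32), affine)
    img.header.set_zooms(vol.voxel_spacing_mm)
    nib.save(img, str(path))


def _record_to_row(p: PatientRecord) -> dict:
    return {
        "patient_id": p.patient_id,
        "sex": p.sex.value,
        "weight_kg": p.weight_kg,
        "height_cm": p.height_cm,
        "pre_injection_activity_mbq": p.pre_injection_activity_mbq,
        "post_injection_activity_mbq": p.post_injection_activity_mbq,
        "measured_time": p.measured_time.strftime(_TIME_FMT),
        "administered_time": p.administered_time.strftime(_TIME_FMT),
        "post_injection_time": p.post_injection_time.strftime(_TIME_FMT),
        "scan_time": p.scan_time.strftime(_TIME_FMT),
        "age_years": p.age_years,
    }


def _row_to_record(row: dict) -> PatientRecord:
    age = row.get("age_years")
    if age is not None and (age == "" or (isinstance(age, float)
                                          and np.isnan(age))):
        age = None
    return PatientRecord(
        patient_id=str(row["patient_id"]),
        sex=Sex(row["sex"]),
        weight_kg=float(row["weight_kg"]),
        height_cm=float(row["height_cm"]),
        pre_injection_activity_mbq=float(row["pre_injection_activity_mbq"]),
        post_injection_activity_mbq=float(row["post_injection_activity_mbq"]),
        measured_time=row["measured_time"],
        administered_time=row["administered_time"],
        post_injection_time=row["post_injection_time"],
        scan_time=row["scan_time"],
        age_years=float(age) if age is not None else None)


def write_patients_csv(patients: list[PatientRecord],
                       path: str | Path) -> None:
    pd.DataFrame([_record_to_row(p) for p in patients]).to_csv(
        path, index=False)


def read_patients_csv(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path)
    return [_row_to_record(row) for row in df.to_dict("records")]


def read_patients_yaml(path: str | Path) -> list[PatientRecord]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict):
        data = data.get("patients", [])
    return [_row_to_record(row) for row in data]


def write_lesion_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    for col in LESION_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    out[LESION_COLUMNS].to_csv(path, index=False)


def read_lesion_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, overlaying the packaged defaults."""
    defaults_path = Path(__file__).parent / "default_config.yaml"
    with open(defaults_path) as fh:
        config = yaml.safe_load(fh)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if (section in config and isinstance(config[section], dict)
                    and isinstance(values, dict)):
                config[section].update(values)
            else:
                config[section] = values
    return config
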