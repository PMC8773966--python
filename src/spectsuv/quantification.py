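"""Decay-corrected activity and lean-body-mass SUV quantification.

Converts reconstructed SPECT activity-concentration volumes (Bq/mL) into
SUVlbm volumes (g/mL).  The normalisation chain is the one used in clinical
bone SPECT-CT quantification:

1. the net injected activity is the syringe activity measured before
   injection minus the residual measured after, each referred to the
   administration time through exponential Tc-99m decay;
2. that net activity is decayed forward to the scan time ("actual
   activity", the SUV denominator);
3. lean body mass follows the James formulae (sex-specific coefficients);
4. SUVlbm = concentration [Bq/mL] x LBM [kg] x 1000 / actual activity [Bq].

All times are wall-clock timestamps at minute resolution on a single clock;
time differences enter the exponentials in hours.  Activities are carried
in MBq and converted to Bq only at the final SUV step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Sex",
    "PatientRecord",
    "DecayCorrection",
    "ActivityVolume",
    "SUVVolume",
    "TC99M_HALF_LIFE_H",
    "decay_rate",
    "lean_body_mass",
    "decay_correction",
    "suv_from_concentration",
    "suv_volume",
]

#: Physical half-life of Tc-99m in hours (not a tunable of the method;
#: overridable wherever a half-life argument is accepted).
TC99M_HALF_LIFE_H = 6.0067

#: The decay-rate numerator.  The clinical formula sheet uses the rounded
#: constant 0.693 rather than ln 2; both are supported (difference < 0.03%).
DECAY_NUMERATOR_DEFAULT = 0.693


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


_TIME_FMT = "%Y-%m-%dT%H:%M"


def _parse_time(value: str | datetime) -> datetime:
    if isinstance(value, datetime):
        return value
    return datetime.strptime(value, _TIME_FMT)


@dataclass(frozen=True)
class PatientRecord:
    """Injection/measurement chronology and body metrics for one patient.

    ``measured_time`` is when the full syringe was assayed
    (``pre_injection_activity``), ``administered_time`` the injection,
    ``post_injection_time`` when the residual was assayed, and
    ``scan_time`` the SPECT acquisition.
    """

    patient_id: str
    sex: Sex
    weight_kg: float
    height_cm: float
    pre_injection_activity_mbq: float
    post_injection_activity_mbq: float
    measured_time: datetime
    administered_time: datetime
    post_injection_time: datetime
    scan_time: datetime
    age_years: float | None = None

    def __post_init__(self) -> None:
        for name in ("measured_time", "administered_time",
                     "post_injection_time", "scan_time"):
            object.__setattr__(self, name, _parse_time(getattr(self, name)))
        object.__setattr__(self, "sex", Sex(self.sex))
        if self.weight_kg <= 0 or self.height_cm <= 0:
            raise ValueError(
                f"patient {self.patient_id!r}: weight and height must be "
                f"positive (got {self.weight_kg} kg, {self.height_cm} cm)")
        if self.post_injection_activity_mbq < 0:
            raise ValueError(
                f"patient {self.patient_id!r}: residual activity negative")
        if self.pre_injection_activity_mbq <= self.post_injection_activity_mbq:
            raise ValueError(
                f"patient {self.patient_id!r}: pre-injection activity must "
                "exceed the residual")
        if not (self.measured_time <= self.administered_time
                <= self.post_injection_time <= self.scan_time):
            raise ValueError(
                f"patient {self.patient_id!r}: timestamps must be ordered "
                "measured <= administered <= post-injection <= scan")

    @property
    def lean_body_mass_kg(self) -> float:
        return lean_body_mass(self.weight_kg, self.height_cm, self.sex)


@dataclass(frozen=True)
class DecayCorrection:
    """The four decay factors and the resulting actual activity (MBq)."""

    lam: float            # per-hour decay rate
    decay1: float         # syringe assay -> administration, in (0, 1]
    decay2: float         # residual assay -> syringe-assay reference, >= 1
    decay_scan: float     # administration -> scan, in (0, 1]
    actual_activity_mbq: float


@dataclass
class ActivityVolume:
    """3-D activity-concentration grid in Bq/mL with physical spacing (mm)."""

    grid: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ValueError("activity grid must be 3-D")
        if np.any(self.grid < 0):
            raise ValueError("activity concentrations must be non-negative")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")


@dataclass
class SUVVolume:
    """3-D SUVlbm grid in g/mL, shape and spacing inherited from its source."""

    grid: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    patient_id: str
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)


def decay_rate(half_life_h: float,
               numerator: float = DECAY_NUMERATOR_DEFAULT) -> float:
    """Per-hour decay rate lambda = numerator / half-life.

    The default numerator is the rounded 0.693 of the clinical formula
    sheet; pass ``numerator=math.log(2)`` for the exact rate.
    """
    if half_life_h <= 0:
        raise ValueError(f"half-life must be positive, got {half_life_h}")
    return numerator / half_life_h


def lean_body_mass(weight_kg: float, height_cm: float, sex: Sex | str) -> float:
    """James lean body mass in kg.

    female: 1.07*W - 148*(W/H)^2;  male: 1.10*W - 120*(W/H)^2
    with W in kg and H in cm.
    """
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    ratio2 = (weight_kg / height_cm) ** 2
    if Sex(sex) is Sex.FEMALE:
        lbm = 1.07 * weight_kg - 148.0 * ratio2
    else:
        lbm = 1.10 * weight_kg - 120.0 * ratio2
    if lbm <= 0:
        raise ValueError(
            f"lean body mass non-positive for weight={weight_kg} kg, "
            f"height={height_cm} cm, sex={Sex(sex).value}")
    return lbm


def _hours(later: datetime, earlier: datetime) -> float:
    return (later - earlier).total_seconds() / 3600.0


def decay_correction(patient: PatientRecord,
                     half_life_h: float = TC99M_HALF_LIFE_H,
                     numerator: float = DECAY_NUMERATOR_DEFAULT,
                     ) -> DecayCorrection:
    """Decay-correct the net injected activity to scan time.

    decay1 refers the syringe assay to administration time (exponent
    non-positive), decay2 refers the residual assay back to the syringe
    reference (exponent non-negative), decay_scan carries the net activity
    from administration to scan:

        actual = decay_scan * decay1 * (measured - decay2 * residual)
    """
    lam = decay_rate(half_life_h, numerator)
    decay1 = math.exp(lam * _hours(patient.measured_time,
                                   patient.administered_time))
    decay2 = math.exp(lam * _hours(patient.post_injection_time,
                                   patient.measured_time))
    decay_scan = math.exp(lam * _hours(patient.administered_time,
                                       patient.scan_time))
    actual = decay_scan * decay1 * (
        patient.pre_injection_activity_mbq
        - decay2 * patient.post_injection_activity_mbq)
    if actual <= 0:
        raise ValueError(
            f"patient {patient.patient_id!r}: decay-corrected residual "
            "exceeds the measured activity (actual activity <= 0)")
    return DecayCorrection(lam=lam, decay1=decay1, decay2=decay2,
                           decay_scan=decay_scan, actual_activity_mbq=actual)


def suv_from_concentration(concentration_bq_ml: float | np.ndarray,
                           lbm_kg: float,
                           actual_activity_mbq: float):
    """SUVlbm in g/mL from an activity concentration in Bq/mL.

    SUV = C [Bq/mL] * LBM [kg] * 1000 [g/kg] / actual activity [Bq].
    Accepts scalars or arrays (elementwise).
    """
    if actual_activity_mbq <= 0:
        raise ValueError("actual activity must be positive")
    if lbm_kg <= 0:
        raise ValueError("lean body mass must be positive")
    conc = np.asarray(concentration_bq_ml, dtype=float)
    if np.any(conc < 0):
        raise ValueError("activity concentration must be non-negative")
    actual_bq = actual_activity_mbq * 1.0e6
    suv = conc * lbm_kg * 1000.0 / actual_bq
    if np.isscalar(concentration_bq_ml):
        return float(suv)
    return suv


def suv_volume(vol: ActivityVolume, patient: PatientRecord,
               half_life_h: float = TC99M_HALF_LIFE_H,
               numerator: float = DECAY_NUMERATOR_DEFAULT) -> SUVVolume:
    """Voxelwise SUVlbm conversion of an activity volume."""
    corr = decay_correction(patient, half_life_h, numerator)
    lbm = patient.lean_body_mass_kg
    grid = suv_from_concentration(vol.grid.astype(float), lbm,
                                  corr.actual_activity_mbq)
    return SUVVolume(grid=np.asarray(grid, dtype=np.float32),
                     voxel_spacing_mm=vol.voxel_spacing_mm,
                     patient_id=patient.patient_id,
                     origin_mm=vol.origin_mm)
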