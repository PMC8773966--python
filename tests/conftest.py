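import numpy as np
import pytest

from spectsuv.quantification import PatientRecord, Sex


@pytest.fixture
def worked_patient() -> PatientRecord:
    """Syringe 700 MBq assayed 09:00, injected 09:05, residual 20 MBq
    assayed 09:10, scanned 12:05 — the hand-checked example patient."""
    return PatientRecord(
        patient_id="worked", sex=Sex.FEMALE,
        weight_kg=70.0, height_cm=170.0,
        pre_injection_activity_mbq=700.0,
        post_injection_activity_mbq=20.0,
        measured_time="2021-03-01T09:00",
        administered_time="2021-03-01T09:05",
        post_injection_time="2021-03-01T09:10",
        scan_time="2021-03-01T12:05")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210301)
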