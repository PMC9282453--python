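import numpy as np
import pytest

from hepanorm.cohort import Cohort, PatientRecord, Sex


def make_record(pid="P1", age=50.0, sex=Sex.MALE, rois=(2.0, 2.1, 2.2),
                aorta=4.0, portal_vein=5.0) -> PatientRecord:
    return PatientRecord(
        patient_id=pid, age=age, sex=sex,
        roi_s3=rois[0], roi_s4b=rois[1], roi_s7=rois[2],
        aorta=aorta, portal_vein=portal_vein,
    )


def random_cohort(rng: np.random.Generator, n: int) -> Cohort:
    records = []
    for i in range(n):
        records.append(
            make_record(
                pid=f"R{i:04d}",
                age=float(rng.uniform(17, 86)),
                sex=Sex.FEMALE if rng.random() < 0.4 else Sex.MALE,
                rois=tuple(rng.uniform(0.5, 4.0, size=3)),
                aorta=float(rng.uniform(2.0, 7.0)),
                portal_vein=float(rng.uniform(2.5, 8.0)),
            )
        )
    return Cohort(records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def six_patient_cohort():
    """Small hand-checkable cohort used by the report tests."""
    rows = [
        # pid, age, sex, s3, s4b, s7, aorta, pv
        ("A1", 30.0, Sex.MALE, 1.8, 1.9, 2.0, 4.0, 4.5),
        ("A2", 45.0, Sex.MALE, 2.0, 2.1, 2.2, 3.8, 4.2),
        ("A3", 60.0, Sex.MALE, 1.7, 1.8, 1.6, 4.2, 4.8),
        ("B1", 35.0, Sex.FEMALE, 2.4, 2.5, 2.6, 5.0, 5.6),
        ("B2", 55.0, Sex.FEMALE, 2.2, 2.3, 2.4, 5.2, 6.0),
        ("B3", 70.0, Sex.FEMALE, 2.1, 2.0, 2.2, 4.8, 5.4),
    ]
    return Cohort([
        make_record(pid=p, age=a, sex=s, rois=(x, y, z), aorta=ao, portal_vein=pv)
        for p, a, s, x, y, z, ao, pv in rows
    ])
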