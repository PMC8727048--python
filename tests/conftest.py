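import datetime as dt

import pytest
from hypothesis import settings

from hivphen.algorithms import AlgorithmConfig
from hivphen.data_model import (
    DiagnosisEvent,
    LabEvent,
    MedEvent,
    PatientRecord,
    Setting,
    derive_lab,
    derive_med,
)
from hivphen.terminology import CodeSystem, default_terminology

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

D0 = dt.date(2015, 1, 1)


@pytest.fixture(scope="session")
def term():
    return default_terminology()


@pytest.fixture()
def cfg(term):
    return AlgorithmConfig(terminology=term)


def day(offset: int) -> dt.date:
    return D0 + dt.timedelta(days=offset)


def make_record(patient_id="P0", birth_year=1980, dx=(), labs=(), meds=()):
    """Build a PatientRecord from compact event tuples.

    dx:   (offset_days, code, setting[, system])
    labs: (offset_days, test_name, value)
    meds: (offset_days, drug_name[, days_supply])
    """
    term = default_terminology()
    diagnoses = []
    for item in dx:
        offset, code, setting = item[0], item[1], item[2]
        system = item[3] if len(item) > 3 else CodeSystem.ICD10
        diagnoses.append(
            DiagnosisEvent(date=day(offset), system=system, code=code,
                           setting=Setting(setting))
        )
    lab_events = [
        derive_lab(LabEvent(date=day(o), test_name=name, value=value), term)
        for o, name, value in labs
    ]
    med_events = []
    for item in meds:
        offset, name = item[0], item[1]
        supply = item[2] if len(item) > 2 else 30
        med_events.append(
            derive_med(MedEvent(date=day(offset), drug_name=name, days_supply=supply), term)
        )
    return PatientRecord(
        patient_id=patient_id,
        birth_date=dt.date(birth_year, 6, 15),
        diagnoses=diagnoses,
        labs=lab_events,
        medications=med_events,
    )
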