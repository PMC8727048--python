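"""Normalized longitudinal EHR records and the flat-table exchange format.

A cohort is exchanged as four UTF-8 comma-delimited tables with mandatory
headers (RFC 4180 quoting, ISO 8601 dates):

``patients.csv``
    patient_id, birth_date, gender, race, ethnicity, marital_status,
    insurance, region, urban_rural
``diagnoses.csv``
    patient_id, date, code_system, code, setting
``labs.csv``
    patient_id, date, test_name, value, units
``meds.csv``
    patient_id, date, drug_name, days_supply

Lab categories/interpretations and medication ingredient sets are *derived*
fields, recomputed on load from the terminology in force; they are never
stored in the exchange tables.  Unparseable rows are skipped with a logged
count — loading never silently drops data.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from .terminology import (
    CodeParseError,
    CodeSystem,
    LabCategory,
    LabInterpretation,
    TerminologyConfig,
    classify_lab_test,
    interpret_lab,
    normalize_code,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Gender",
    "Setting",
    "DiagnosisEvent",
    "LabEvent",
    "MedEvent",
    "PatientRecord",
    "Cohort",
    "CohortFormatError",
    "read_cohort",
    "write_cohort",
    "read_gold",
    "write_gold",
    "filter_eligible",
    "age_on",
]

PATIENT_COLUMNS = [
    "patient_id", "birth_date", "gender", "race", "ethnicity",
    "marital_status", "insurance", "region", "urban_rural",
]
DIAGNOSIS_COLUMNS = ["patient_id", "date", "code_system", "code", "setting"]
LAB_COLUMNS = ["patient_id", "date", "test_name", "value", "units"]
MED_COLUMNS = ["patient_id", "date", "drug_name", "days_supply"]

TABLE_FILES = {
    "patients": "patients.csv",
    "diagnoses": "diagnoses.csv",
    "labs": "labs.csv",
    "meds": "meds.csv",
}


class CohortFormatError(ValueError):
    """Fatal problem in the exchange tables (missing file/column, duplicate ids)."""


class Gender(str, Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


class Setting(str, Enum):
    INPATIENT = "INPATIENT"
    OUTPATIENT = "OUTPATIENT"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class DiagnosisEvent:
    date: dt.date
    system: CodeSystem
    code: str  # normalized: uppercase, dot-free
    setting: Setting = Setting.UNKNOWN


@dataclass(frozen=True)
class LabEvent:
    date: dt.date
    test_name: str
    value: str
    units: str = ""
    # derived from the terminology in force
    category: LabCategory = LabCategory.OTHER
    interpretation: Optional[LabInterpretation] = None


@dataclass(frozen=True)
class MedEvent:
    date: dt.date
    drug_name: str
    ingredients: frozenset = frozenset()  # derived, normalized
    days_supply: Optional[int] = None


@dataclass
class PatientRecord:
    patient_id: str
    birth_date: dt.date
    gender: Gender = Gender.UNKNOWN
    race: str = ""
    ethnicity: str = ""
    marital_status: str = ""
    insurance: str = ""
    region: str = ""
    urban_rural: str = ""
    diagnoses: List[DiagnosisEvent] = field(default_factory=list)
    labs: List[LabEvent] = field(default_factory=list)
    medications: List[MedEvent] = field(default_factory=list)

    def event_dates(self) -> List[dt.date]:
        return (
            [d.date for d in self.diagnoses]
            + [l.date for l in self.labs]
            + [m.date for m in self.medications]
        )

    def latest_event_date(self) -> Optional[dt.date]:
        dates = self.event_dates()
        return max(dates) if dates else None


@dataclass
class Cohort:
    patients: List[PatientRecord]
    provenance: str = ""
    terminology_version: str = ""

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise CohortFormatError("duplicate patient_id in cohort")

    def __len__(self) -> int:
        return len(self.patients)

    def ids(self) -> List[str]:
        return [p.patient_id for p in self.patients]


def age_on(birth_date: dt.date, ref: dt.date) -> int:
    """Completed years of age on ``ref``."""
    years = ref.year - birth_date.year
    if (ref.month, ref.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def derive_lab(event: LabEvent, terminology: TerminologyConfig) -> LabEvent:
    category = classify_lab_test(event.test_name, terminology.lab_catalog)
    interp = (
        interpret_lab(category, event.value, event.units or None, terminology)
        if category is not LabCategory.OTHER
        else None
    )
    return replace(event, category=category, interpretation=interp)


def derive_med(event: MedEvent, terminology: TerminologyConfig) -> MedEvent:
    return replace(event, ingredients=terminology.med_catalog.expand(event.drug_name))


def _read_table(path: Path, columns: List[str]) -> pd.DataFrame:
    if not path.exists():
        raise CohortFormatError(f"missing table file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in columns:
        if col not in df.columns:
            raise CohortFormatError(f"{path.name}: missing column {col!r}")
    return df


def _parse_date(text: str) -> dt.date:
    return dt.date.fromisoformat(text.strip())


def read_cohort(directory: Path, terminology: TerminologyConfig) -> Cohort:
    """Read the four-table format, derive lab/med fields, and join by patient_id.

    Rows that fail to parse or reference an unknown patient are skipped with a
    logged count; duplicate patient ids and missing files/columns are fatal.
    """
    directory = Path(directory)
    patients_df = _read_table(directory / TABLE_FILES["patients"], PATIENT_COLUMNS)
    dx_df = _read_table(directory / TABLE_FILES["diagnoses"], DIAGNOSIS_COLUMNS)
    lab_df = _read_table(directory / TABLE_FILES["labs"], LAB_COLUMNS)
    med_df = _read_table(directory / TABLE_FILES["meds"], MED_COLUMNS)

    if patients_df["patient_id"].duplicated().any():
        dupes = patients_df.loc[patients_df["patient_id"].duplicated(), "patient_id"]
        raise CohortFormatError(f"duplicate patient_id in patients.csv: {sorted(set(dupes))}")

    records: Dict[str, PatientRecord] = {}
    skipped = {"patients": 0, "diagnoses": 0, "labs": 0, "meds": 0}
    for row in patients_df.itertuples(index=False):
        try:
            gender = Gender(row.gender) if row.gender else Gender.UNKNOWN
            records[row.patient_id] = PatientRecord(
                patient_id=row.patient_id,
                birth_date=_parse_date(row.birth_date),
                gender=gender,
                race=row.race,
                ethnicity=row.ethnicity,
                marital_status=row.marital_status,
                insurance=row.insurance,
                region=row.region,
                urban_rural=row.urban_rural,
            )
        except (ValueError, KeyError) as exc:
            skipped["patients"] += 1
            logger.warning("patients.csv: skipping row for %r (%s)", row.patient_id, exc)

    for row in dx_df.itertuples(index=False):
        if row.patient_id not in records:
            skipped["diagnoses"] += 1
            logger.warning("diagnoses.csv: unknown patient_id %r, row skipped", row.patient_id)
            continue
        try:
            system = CodeSystem(row.code_system)
            event = DiagnosisEvent(
                date=_parse_date(row.date),
                system=system,
                code=normalize_code(row.code, system),
                setting=Setting(row.setting) if row.setting else Setting.UNKNOWN,
            )
        except (ValueError, CodeParseError) as exc:
            skipped["diagnoses"] += 1
            logger.warning("diagnoses.csv: skipping row for %r (%s)", row.patient_id, exc)
            continue
        records[row.patient_id].diagnoses.append(event)

    for row in lab_df.itertuples(index=False):
        if row.patient_id not in records:
            skipped["labs"] += 1
            logger.warning("labs.csv: unknown patient_id %r, row skipped", row.patient_id)
            continue
        try:
            event = LabEvent(
                date=_parse_date(row.date),
                test_name=row.test_name,
                value=row.value,
                units=row.units,
            )
        except ValueError as exc:
            skipped["labs"] += 1
            logger.warning("labs.csv: skipping row for %r (%s)", row.patient_id, exc)
            continue
        derived = derive_lab(event, terminology)
        if derived.interpretation is not None and not derived.interpretation.usable:
            logger.warning(
                "labs.csv: unusable %s value %r for patient %r (kept, contributes to no criterion)",
                derived.category.value, row.value, row.patient_id,
            )
        records[row.patient_id].labs.append(derived)

    for row in med_df.itertuples(index=False):
        if row.patient_id not in records:
            skipped["meds"] += 1
            logger.warning("meds.csv: unknown patient_id %r, row skipped", row.patient_id)
            continue
        try:
            supply = int(row.days_supply) if row.days_supply else None
            if supply is not None and supply <= 0:
                raise ValueError(f"non-positive days_supply {supply}")
            event = MedEvent(
                date=_parse_date(row.date),
                drug_name=row.drug_name,
                days_supply=supply,
            )
        except ValueError as exc:
            skipped["meds"] += 1
            logger.warning("meds.csv: skipping row for %r (%s)", row.patient_id, exc)
            continue
        records[row.patient_id].medications.append(derive_med(event, terminology))

    total_skipped = sum(skipped.values())
    if total_skipped:
        logger.info("read_cohort: skipped rows by table: %s", skipped)
    return Cohort(
        patients=list(records.values()),
        provenance=str(directory),
        terminology_version=terminology.version,
    )


def write_cohort(cohort: Cohort, directory: Path) -> None:
    """Write the four-table format; derived fields are not persisted."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "birth_date": p.birth_date.isoformat(),
                "gender": p.gender.value,
                "race": p.race,
                "ethnicity": p.ethnicity,
                "marital_status": p.marital_status,
                "insurance": p.insurance,
                "region": p.region,
                "urban_rural": p.urban_rural,
            }
            for p in cohort.patients
        ],
        columns=PATIENT_COLUMNS,
    ).to_csv(directory / TABLE_FILES["patients"], index=False)
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "date": d.date.isoformat(),
                "code_system": d.system.value,
                "code": d.code,
                "setting": d.setting.value,
            }
            for p in cohort.patients
            for d in p.diagnoses
        ],
        columns=DIAGNOSIS_COLUMNS,
    ).to_csv(directory / TABLE_FILES["diagnoses"], index=False)
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "date": l.date.isoformat(),
                "test_name": l.test_name,
                "value": l.value,
                "units": l.units,
            }
            for p in cohort.patients
            for l in p.labs
        ],
        columns=LAB_COLUMNS,
    ).to_csv(directory / TABLE_FILES["labs"], index=False)
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "date": m.date.isoformat(),
                "drug_name": m.drug_name,
                "days_supply": "" if m.days_supply is None else m.days_supply,
            }
            for p in cohort.patients
            for m in p.medications
        ],
        columns=MED_COLUMNS,
    ).to_csv(directory / TABLE_FILES["meds"], index=False)


def write_gold(gold: Dict[str, bool], directory: Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"patient_id": pid, "hiv_status": int(status)} for pid, status in gold.items()],
        columns=["patient_id", "hiv_status"],
    ).to_csv(directory / "gold.csv", index=False)


def read_gold(path: Path) -> Dict[str, bool]:
    path = Path(path)
    if path.is_dir():
        path = path / "gold.csv"
    if not path.exists():
        raise CohortFormatError(f"missing gold-standard file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("patient_id", "hiv_status"):
        if col not in df.columns:
            raise CohortFormatError(f"{path.name}: missing column {col!r}")
    return {r.patient_id: bool(int(r.hiv_status)) for r in df.itertuples(index=False)}


def filter_eligible(cohort: Cohort, min_age_years: int = 13) -> Cohort:
    """Retain patients aged >= ``min_age_years`` at their latest recorded event.

    Patients with no events have no reference date and are excluded (logged).
    Idempotent and order-independent.
    """
    kept: List[PatientRecord] = []
    n_no_events = 0
    n_underage = 0
    for p in cohort.patients:
        latest = p.latest_event_date()
        if latest is None:
            n_no_events += 1
            logger.warning("filter_eligible: patient %r has no events, excluded", p.patient_id)
            continue
        if age_on(p.birth_date, latest) >= min_age_years:
            kept.append(p)
        else:
            n_underage += 1
    if n_no_events or n_underage:
        logger.info(
            "filter_eligible: excluded %d patients with no events, %d under age %d",
            n_no_events, n_underage, min_age_years,
        )
    return Cohort(
        patients=kept,
        provenance=cohort.provenance,
        terminology_version=cohort.terminology_version,
    )
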