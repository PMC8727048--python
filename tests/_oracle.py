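"""Independent brute-force evaluation of the five phenotyping rules.

Written directly from the rule definitions over a fixed event vocabulary,
sharing no code with hivphen.algorithms: its own code list, its own test
categorization, its own value parsing and its own drug classification.
Used as the truth oracle for randomized equivalence tests.
"""

import datetime as dt

import numpy as np

from hivphen.data_model import DiagnosisEvent, LabEvent, MedEvent, PatientRecord, Setting
from hivphen.data_model import derive_lab, derive_med
from hivphen.terminology import CodeSystem, default_terminology

# --- fixed vocabulary both sides understand -------------------------------

DATES = [dt.date(2015, 1, 1) + dt.timedelta(days=30 * k) for k in range(4)]

DX_POOL = [
    ("B20", CodeSystem.ICD10, Setting.OUTPATIENT),
    ("B20", CodeSystem.ICD10, Setting.INPATIENT),
    ("Z21", CodeSystem.ICD10, Setting.OUTPATIENT),
    ("R75", CodeSystem.ICD10, Setting.OUTPATIENT),
    ("0420", CodeSystem.ICD9, Setting.OUTPATIENT),
    ("V08", CodeSystem.ICD9, Setting.INPATIENT),
    ("J45909", CodeSystem.ICD10, Setting.OUTPATIENT),  # not an HIV code
    ("I10", CodeSystem.ICD10, Setting.INPATIENT),      # not an HIV code
]

LAB_POOL = [
    ("HIV ANTIBODY SCREEN", "REACTIVE"),
    ("HIV ANTIBODY SCREEN", "NONREACTIVE"),
    ("HIV ANTIBODY SCREEN", "INDETERMINATE"),
    ("HIV 1 WESTERN BLOT", "POSITIVE"),
    ("HIV 1 WESTERN BLOT", "NEGATIVE"),
    ("HIV-1/2 DIFFERENTIATION (GEENIUS)", "POSITIVE"),
    ("HIV 1 RNA QUANT PCR", "5000"),
    ("HIV 1 RNA QUANT PCR", "1,500"),
    ("HIV 1 RNA QUANT PCR", "800"),
    ("HIV 1 RNA QUANT PCR", "<20"),
    ("HIV 1 RNA QUANT PCR", "NOT DETECTED"),
    ("HIV 1 RNA QUANT PCR", ">750000"),
    ("ABSOLUTE CD4 COUNT", "500"),
    ("BASIC METABOLIC PANEL", "12"),
]

MED_POOL = ["biktarvy", "dolutegravir", "truvada", "tenofovir", "lamivudine", "lisinopril"]

# --- the oracle's own terminology -----------------------------------------

_HIV_EXACT = {
    CodeSystem.ICD10: {"B20", "Z21", "R75", "B9735"},
    CodeSystem.ICD9: {"V08", "07953", "79571"},
}
_HIV_PREFIX = {CodeSystem.ICD10: ("O987",), CodeSystem.ICD9: ("042",)}

_SCREEN_TESTS = {"HIV ANTIBODY SCREEN"}
_CONFIRM_TESTS = {"HIV 1 WESTERN BLOT", "HIV-1/2 DIFFERENTIATION (GEENIUS)"}
_VL_TESTS = {"HIV 1 RNA QUANT PCR"}
_CD4_TESTS = {"ABSOLUTE CD4 COUNT"}

_POS_WORDS = {"REACTIVE", "POSITIVE"}

_CORE_DRUGS = {"biktarvy", "dolutegravir"}
_AMBIGUOUS_DRUGS = {"truvada", "tenofovir", "lamivudine"}


def _is_hiv_code(code, system):
    return code in _HIV_EXACT[system] or any(
        code.startswith(p) for p in _HIV_PREFIX[system]
    )


def _vl_above(value, threshold):
    v = value.replace(",", "")
    if v == "NOT DETECTED" or v.startswith("<"):
        return False
    if v.startswith(">"):  # open upper bound: exceeds anything strictly below it
        return threshold < float(v[1:])
    return float(v) > threshold


def oracle_labels(record: PatientRecord, threshold: float = 1000.0) -> dict:
    """Truth-table evaluation of all five rules on one record."""
    hiv_dx = [d for d in record.diagnoses if _is_hiv_code(d.code, d.system)]
    outpatient_dates = {d.date for d in hiv_dx if d.setting is Setting.OUTPATIENT}
    has_inpatient = any(d.setting is Setting.INPATIENT for d in hiv_dx)

    screen_pos = any(
        l.test_name in _SCREEN_TESTS and l.value in _POS_WORDS for l in record.labs
    )
    confirm_pos = any(
        l.test_name in _CONFIRM_TESTS and l.value in _POS_WORDS for l in record.labs
    )
    any_vl = any(l.test_name in _VL_TESTS for l in record.labs)
    any_cd4 = any(l.test_name in _CD4_TESTS for l in record.labs)
    vl_high = any(
        l.test_name in _VL_TESTS and _vl_above(l.value, threshold) for l in record.labs
    )

    drugs = {m.drug_name for m in record.medications}
    any_arv = bool(drugs & (_CORE_DRUGS | _AMBIGUOUS_DRUGS))
    core_arv = bool(drugs & _CORE_DRUGS)

    fultz = len(outpatient_dates) >= 2 or has_inpatient
    paul_lab = (screen_pos and confirm_pos) or vl_high or any_arv
    paul_icd = bool(hiv_dx) and (confirm_pos or vl_high or any_arv)
    kramer_criteria = sum(
        [bool(hiv_dx), screen_pos or confirm_pos or any_vl or any_cd4, any_arv]
    )
    hiv_phen = confirm_pos or vl_high or core_arv

    return {
        "FULTZ_ICD_ONLY": fultz,
        "PAUL_LAB": paul_lab,
        "PAUL_ICD": paul_icd,
        "KRAMER_CRITERIA": kramer_criteria >= 2,
        "HIV_PHEN": hiv_phen,
    }


def random_record(rng: np.random.Generator, pid: str = "PX") -> PatientRecord:
    """A small random record drawn from the fixed vocabulary (<=5 events/type)."""
    term = default_terminology()
    dx = []
    for _ in range(int(rng.integers(0, 5))):
        code, system, setting = DX_POOL[int(rng.integers(len(DX_POOL)))]
        dx.append(DiagnosisEvent(date=DATES[int(rng.integers(4))], system=system,
                                 code=code, setting=setting))
    labs = []
    for _ in range(int(rng.integers(0, 5))):
        name, value = LAB_POOL[int(rng.integers(len(LAB_POOL)))]
        labs.append(derive_lab(
            LabEvent(date=DATES[int(rng.integers(4))], test_name=name, value=value),
            term))
    meds = []
    for _ in range(int(rng.integers(0, 4))):
        drug = MED_POOL[int(rng.integers(len(MED_POOL)))]
        meds.append(derive_med(
            MedEvent(date=DATES[int(rng.integers(4))], drug_name=drug, days_supply=30),
            term))
    return PatientRecord(patient_id=pid, birth_date=dt.date(1980, 6, 15),
                         diagnoses=dx, labs=labs, medications=meds)
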