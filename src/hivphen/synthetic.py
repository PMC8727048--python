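"""Seeded synthetic EHR cohorts with known gold-standard HIV status.

Real HIV cohort data cannot be redistributed, so this module generates
cohorts that emulate the *diagnostic trajectories* the phenotyping
algorithms must discriminate: complete diagnostic trails, lab-only and
medication-only presentations, ICD code misuse, diagnostic work-ups with
negative results, post-/pre-exposure prophylaxis, hepatitis-B monotherapy,
and gold-positive patients whose HIV evidence lives only in clinical notes
(and is therefore invisible to every structured-data algorithm).

Each archetype makes a structural promise (e.g. ``VL_ONLY`` emits viral
loads above 1000 copies/mL and *no* diagnosis codes, screening results or
medications), and carries a fixed gold label, so the expected decision of
every algorithm on every archetype is a hand-derivable truth table
(:data:`EXPECTED_LABELS`).

Only threshold crossings matter to the algorithms, so event-level details
(counts of tests, inter-event gaps, value distributions) are plain
parameterized defaults: viral loads for untreated gold-positive archetypes
are log-uniform on 10^3.1..10^6 copies/mL, CD4 counts uniform in plausible
clinical ranges, regimens are standard combination products.

Generation is reproducible: one root seed, one substream per patient index,
so the same seed and spec produce byte-identical tables.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .algorithms import Algorithm
from .data_model import (
    Cohort,
    DiagnosisEvent,
    Gender,
    LabEvent,
    MedEvent,
    PatientRecord,
    Setting,
    derive_lab,
    derive_med,
)
from .terminology import CodeSystem, TerminologyConfig, default_terminology

logger = logging.getLogger(__name__)

__all__ = [
    "Archetype",
    "ARCHETYPE_GOLD",
    "EXPECTED_LABELS",
    "CohortSpec",
    "DEFAULT_MIXTURE",
    "DEMOGRAPHIC_PRESETS",
    "generate_cohort",
    "expected_label",
    "chart_review_360_spec",
    "CHART_REVIEW_360_COUNTS",
]


class Archetype(str, Enum):
    FULL_TRAIL = "FULL_TRAIL"            # screen+ -> confirm+ -> VL>1000 -> ART, ICD coded
    VL_ONLY = "VL_ONLY"                  # viral loads >1000 only, no codes/screens/meds
    ARV_ONLY = "ARV_ONLY"                # treatment-sufficient regimen only
    CONFIRM_ONLY = "CONFIRM_ONLY"        # positive confirmatory test only
    ICD_ONLY_MISUSE = "ICD_ONLY_MISUSE"  # HIV codes without clinical evidence (gold-negative)
    WORKUP_ONLY = "WORKUP_ONLY"          # ICD code + CD4/VL ordered, results negative/low
    PEP = "PEP"                          # short full regimen after exposure, negative tests
    PREP = "PREP"                        # ambiguous two-drug regimen, negative screens
    HBV_MONO = "HBV_MONO"                # single ambiguous agent for hepatitis B
    NOTES_ONLY_HIV = "NOTES_ONLY_HIV"    # gold-positive, no structured HIV evidence
    BACKGROUND = "BACKGROUND"            # general-population patient


ARCHETYPE_GOLD: Dict[Archetype, bool] = {
    Archetype.FULL_TRAIL: True,
    Archetype.VL_ONLY: True,
    Archetype.ARV_ONLY: True,
    Archetype.CONFIRM_ONLY: True,
    Archetype.ICD_ONLY_MISUSE: False,
    Archetype.WORKUP_ONLY: False,
    Archetype.PEP: False,
    Archetype.PREP: False,
    Archetype.HBV_MONO: False,
    Archetype.NOTES_ONLY_HIV: True,
    Archetype.BACKGROUND: False,
}

# Hand-derived truth table: expected label of each algorithm on each archetype
# under the default configuration (VL threshold 1000 copies/mL).  Tuple order:
# (FULTZ_ICD_ONLY, PAUL_LAB, PAUL_ICD, KRAMER_CRITERIA, HIV_PHEN).
_T = True
_F = False
_EXPECTED: Dict[Archetype, Tuple[bool, bool, bool, bool, bool]] = {
    Archetype.FULL_TRAIL:      (_T, _T, _T, _T, _T),
    Archetype.VL_ONLY:         (_F, _T, _F, _F, _T),
    Archetype.ARV_ONLY:        (_F, _T, _F, _F, _T),
    Archetype.CONFIRM_ONLY:    (_F, _F, _F, _F, _T),
    Archetype.ICD_ONLY_MISUSE: (_T, _F, _F, _F, _F),
    Archetype.WORKUP_ONLY:     (_F, _F, _F, _T, _F),
    Archetype.PEP:             (_F, _T, _F, _F, _T),
    Archetype.PREP:            (_F, _T, _F, _F, _F),
    Archetype.HBV_MONO:        (_F, _T, _F, _F, _F),
    Archetype.NOTES_ONLY_HIV:  (_F, _F, _F, _F, _F),
    Archetype.BACKGROUND:      (_F, _F, _F, _F, _F),
}
_ALG_ORDER = (
    Algorithm.FULTZ_ICD_ONLY,
    Algorithm.PAUL_LAB,
    Algorithm.PAUL_ICD,
    Algorithm.KRAMER_CRITERIA,
    Algorithm.HIV_PHEN,
)
EXPECTED_LABELS: Dict[Tuple[Archetype, Algorithm], str] = {
    (arch, alg): ("POSITIVE" if val else "NEGATIVE")
    for arch, row in _EXPECTED.items()
    for alg, val in zip(_ALG_ORDER, row)
}


def expected_label(archetype: Archetype, algorithm: Algorithm) -> str:
    """Hand-derived expected classification under default archetype parameters."""
    return EXPECTED_LABELS[(Archetype(archetype), Algorithm(algorithm))]


DEMOGRAPHIC_PRESETS: Dict[str, Dict[str, Dict[str, float]]] = {
    # Surveillance-style marginals for people with HIV (public case-count style)
    "national_surveillance": {
        "gender": {"MALE": 0.7642, "FEMALE": 0.2358},
        "race": {"BLACK": 0.4061, "WHITE": 0.2919, "OTHER": 0.3020},
    },
    "local_surveillance": {
        "gender": {"MALE": 0.7545, "FEMALE": 0.2455},
        "race": {"BLACK": 0.4943, "WHITE": 0.1834, "OTHER": 0.3223},
    },
    # A generic outpatient-EHR background population
    "ehr_default": {
        "gender": {"FEMALE": 0.54, "MALE": 0.45, "OTHER": 0.005, "UNKNOWN": 0.005},
        "race": {"WHITE": 0.50, "BLACK": 0.24, "ASIAN": 0.08, "OTHER": 0.18},
        "ethnicity": {"NON-HISPANIC": 0.72, "HISPANIC": 0.23, "UNKNOWN": 0.05},
        "marital_status": {"SINGLE": 0.40, "MARRIED": 0.45, "DIVORCED": 0.10, "WIDOWED": 0.05},
        "insurance": {"PRIVATE": 0.55, "MEDICAID": 0.20, "MEDICARE": 0.15, "UNINSURED": 0.10},
        "region": {"SOUTH": 0.40, "NORTHEAST": 0.20, "MIDWEST": 0.20, "WEST": 0.20},
        "urban_rural": {"URBAN": 0.82, "RURAL": 0.18},
    },
}

DEFAULT_MIXTURE: Dict[Archetype, float] = {
    Archetype.FULL_TRAIL: 0.030,
    Archetype.VL_ONLY: 0.010,
    Archetype.ARV_ONLY: 0.010,
    Archetype.CONFIRM_ONLY: 0.005,
    Archetype.ICD_ONLY_MISUSE: 0.005,
    Archetype.WORKUP_ONLY: 0.005,
    Archetype.PEP: 0.005,
    Archetype.PREP: 0.010,
    Archetype.HBV_MONO: 0.005,
    Archetype.NOTES_ONLY_HIV: 0.005,
    Archetype.BACKGROUND: 0.910,
}

# Preset built so that HIV-Phen's confusion counts against gold are
# (tp, fn, fp, tn) = (162, 4, 9, 185) by construction: 162 structurally
# detectable gold-positives, 4 notes-only false negatives, 9 PEP false
# positives, 185 gold-negatives the algorithm correctly rejects.
CHART_REVIEW_360_COUNTS: Dict[Archetype, int] = {
    Archetype.FULL_TRAIL: 60,
    Archetype.VL_ONLY: 40,
    Archetype.ARV_ONLY: 40,
    Archetype.CONFIRM_ONLY: 22,
    Archetype.NOTES_ONLY_HIV: 4,
    Archetype.PEP: 9,
    Archetype.ICD_ONLY_MISUSE: 6,
    Archetype.WORKUP_ONLY: 5,
    Archetype.PREP: 8,
    Archetype.HBV_MONO: 4,
    Archetype.BACKGROUND: 162,
}


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort: size, archetype mixture, demographics, seed."""

    n: int
    seed: int
    mixture: Mapping[Archetype, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    counts: Optional[Mapping[Archetype, int]] = None  # exact counts override the mixture
    demographics: str | Mapping[str, Mapping[str, float]] = "ehr_default"
    date_window: Tuple[dt.date, dt.date] = (dt.date(2010, 1, 1), dt.date(2019, 12, 31))

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.counts is not None:
            total = sum(self.counts.values())
            if total != self.n:
                raise ValueError(f"counts sum to {total}, expected n={self.n}")
        else:
            total = sum(self.mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixture weights sum to {total}, expected 1")
            if any(w < 0 for w in self.mixture.values()):
                raise ValueError("mixture weights must be non-negative")

    def demographic_tables(self) -> Dict[str, Dict[str, float]]:
        base = dict(DEMOGRAPHIC_PRESETS["ehr_default"])
        override = (
            DEMOGRAPHIC_PRESETS[self.demographics]
            if isinstance(self.demographics, str)
            else self.demographics
        )
        base.update(override)
        return base


def chart_review_360_spec(seed: int = 0) -> CohortSpec:
    """The 360-patient chart-review evaluation preset (exact archetype counts)."""
    return CohortSpec(n=360, seed=seed, counts=dict(CHART_REVIEW_360_COUNTS))


# --- event builders -------------------------------------------------------

_SCREEN_NAMES = ["HIV 1/2 AG/AB 4TH GEN", "HIV ANTIBODY SCREEN", "RAPID HIV TEST"]
_CONFIRM_NAMES = ["HIV-1/2 DIFFERENTIATION (GEENIUS)", "HIV 1 WESTERN BLOT", "HIV MULTISPOT ASSAY"]
_VL_NAMES = ["HIV 1 RNA QUANT PCR", "HIV RNA QUANTITATIVE", "HIV VIRAL LOAD"]
_CD4_NAMES = ["ABSOLUTE CD4 COUNT", "CD4 LYMPHOCYTE COUNT"]
_BENIGN_LABS = ["BASIC METABOLIC PANEL", "COMPLETE BLOOD COUNT", "HEMOGLOBIN A1C", "LIPID PANEL"]
_BENIGN_DX10 = ["I10", "E119", "J45909", "K219", "M545"]
_BENIGN_MEDS = ["lisinopril", "metformin", "atorvastatin", "albuterol"]
_HIV_CODES_10 = ["B20", "Z21", "R75"]
_ART_COMBOS = ["biktarvy", "triumeq", "atripla", "dovato"]


def _pick(rng: np.random.Generator, items: List[str]) -> str:
    return items[int(rng.integers(len(items)))]


def _high_vl(rng: np.random.Generator) -> int:
    # log-uniform 10^3.1 .. 10^6: strictly above the 1000 copies/mL cut-off
    return int(round(10 ** rng.uniform(3.1, 6.0)))


def _day(rng: np.random.Generator, start: dt.date, span_days: int) -> dt.date:
    return start + dt.timedelta(days=int(rng.integers(span_days)))


class _Builder:
    def __init__(self, rng: np.random.Generator, t0: dt.date):
        self.rng = rng
        self.t0 = t0
        self.dx: List[DiagnosisEvent] = []
        self.labs: List[LabEvent] = []
        self.meds: List[MedEvent] = []

    def lab(self, offset: int, name: str, value: str, units: str = "") -> None:
        self.labs.append(
            LabEvent(date=self.t0 + dt.timedelta(days=offset), test_name=name,
                     value=value, units=units)
        )

    def screen(self, offset: int, result: str) -> None:
        self.lab(offset, _pick(self.rng, _SCREEN_NAMES), result)

    def confirm(self, offset: int, result: str) -> None:
        self.lab(offset, _pick(self.rng, _CONFIRM_NAMES), result)

    def vl(self, offset: int, value: str) -> None:
        self.lab(offset, _pick(self.rng, _VL_NAMES), value, "copies/mL")

    def cd4(self, offset: int, value: int) -> None:
        self.lab(offset, _pick(self.rng, _CD4_NAMES), str(value), "cells/uL")

    def diagnosis(self, offset: int, code: str, setting: Setting,
                  system: CodeSystem = CodeSystem.ICD10) -> None:
        self.dx.append(
            DiagnosisEvent(date=self.t0 + dt.timedelta(days=offset), system=system,
                           code=code, setting=setting)
        )

    def med(self, offset: int, name: str, days_supply: int = 30) -> None:
        self.meds.append(
            MedEvent(date=self.t0 + dt.timedelta(days=offset), drug_name=name,
                     days_supply=days_supply)
        )

    def benign_noise(self, n_dx: int, n_labs: int, n_meds: int) -> None:
        for _ in range(n_dx):
            self.diagnosis(int(self.rng.integers(0, 300)),
                           _pick(self.rng, _BENIGN_DX10), Setting.OUTPATIENT)
        for _ in range(n_labs):
            self.lab(int(self.rng.integers(0, 300)), _pick(self.rng, _BENIGN_LABS),
                     str(int(self.rng.integers(1, 300))))
        for _ in range(n_meds):
            self.med(int(self.rng.integers(0, 300)), _pick(self.rng, _BENIGN_MEDS))


def _build_full_trail(b: _Builder) -> None:
    rng = b.rng
    b.screen(0, "REACTIVE")
    b.confirm(7, "POSITIVE")
    vl = _high_vl(rng)
    # exercise the tolerant number parser with occasional thousands separators
    b.vl(14, f"{vl:,}" if rng.random() < 0.3 else str(vl))
    b.cd4(14, int(rng.integers(120, 800)))
    b.diagnosis(14, _pick(rng, _HIV_CODES_10), Setting.OUTPATIENT)
    b.diagnosis(45, _pick(rng, _HIV_CODES_10), Setting.OUTPATIENT)
    if rng.random() < 0.3:
        b.diagnosis(0, "B20", Setting.INPATIENT)
    combo = _pick(rng, _ART_COMBOS)
    for k in range(6):
        b.med(21 + 30 * k, combo, 30)
    if rng.random() < 0.7:
        b.vl(120, "<20")  # suppressed on treatment


def _build_vl_only(b: _Builder) -> None:
    for k in range(int(b.rng.integers(1, 4))):
        b.vl(40 * k, str(_high_vl(b.rng)))


def _build_arv_only(b: _Builder) -> None:
    combo = _pick(b.rng, _ART_COMBOS)
    for k in range(int(b.rng.integers(4, 9))):
        b.med(30 * k, combo, 30)


def _build_confirm_only(b: _Builder) -> None:
    b.confirm(0, "POSITIVE")


def _build_icd_only_misuse(b: _Builder) -> None:
    rng = b.rng
    n = int(rng.integers(2, 5))
    for k in range(n):
        b.diagnosis(30 * k, _pick(rng, _HIV_CODES_10), Setting.OUTPATIENT)
    if rng.random() < 0.3:
        b.diagnosis(5, _pick(rng, _HIV_CODES_10), Setting.INPATIENT)


def _build_workup_only(b: _Builder) -> None:
    rng = b.rng
    b.diagnosis(0, _pick(rng, _HIV_CODES_10), Setting.OUTPATIENT)  # single code only
    b.cd4(0, int(rng.integers(300, 1200)))
    if rng.random() < 0.3:
        b.vl(0, str(int(rng.integers(25, 1000))))  # detectable but below threshold
    else:
        b.vl(0, "NOT DETECTED")
    if rng.random() < 0.5:
        b.screen(0, "NONREACTIVE")


def _build_pep(b: _Builder) -> None:
    # full treatment regimen, single ~28-day course, surrounding negative tests
    b.screen(0, "NONREACTIVE")
    b.med(0, "truvada", 28)
    b.med(0, "dolutegravir", 28)
    b.screen(30, "NONREACTIVE")


def _build_prep(b: _Builder) -> None:
    rng = b.rng
    for k in range(int(rng.integers(3, 10))):
        b.med(30 * k, "truvada" if rng.random() < 0.7 else "descovy", 30)
    for k in range(int(rng.integers(1, 4))):
        b.screen(90 * k, "NONREACTIVE")


def _build_hbv_mono(b: _Builder) -> None:
    rng = b.rng
    agent = "tenofovir disoproxil" if rng.random() < 0.7 else "lamivudine"
    for k in range(int(rng.integers(4, 9))):
        b.med(30 * k, agent, 30)
    b.diagnosis(0, "B181", Setting.OUTPATIENT)
    b.diagnosis(90, "B181", Setting.OUTPATIENT)


def _build_notes_only(b: _Builder) -> None:
    # HIV status lives only in note text: structured record is benign
    b.benign_noise(1, 1, 1)


def _build_background(b: _Builder) -> None:
    rng = b.rng
    b.benign_noise(int(rng.integers(1, 4)), int(rng.integers(0, 3)),
                   int(rng.integers(0, 3)))


_BUILDERS = {
    Archetype.FULL_TRAIL: _build_full_trail,
    Archetype.VL_ONLY: _build_vl_only,
    Archetype.ARV_ONLY: _build_arv_only,
    Archetype.CONFIRM_ONLY: _build_confirm_only,
    Archetype.ICD_ONLY_MISUSE: _build_icd_only_misuse,
    Archetype.WORKUP_ONLY: _build_workup_only,
    Archetype.PEP: _build_pep,
    Archetype.PREP: _build_prep,
    Archetype.HBV_MONO: _build_hbv_mono,
    Archetype.NOTES_ONLY_HIV: _build_notes_only,
    Archetype.BACKGROUND: _build_background,
}


def _draw_categorical(rng: np.random.Generator, table: Mapping[str, float]) -> str:
    keys = sorted(table)
    probs = np.array([table[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def _make_patient(
    index: int,
    archetype: Archetype,
    spec: CohortSpec,
    terminology: TerminologyConfig,
) -> PatientRecord:
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1, index)))
    demo = spec.demographic_tables()
    start, end = spec.date_window
    span = max((end - start).days - 400, 1)
    t0 = _day(rng, start, span)
    age = int(rng.integers(18, 76))
    birth_year = t0.year - age
    birth_date = dt.date(birth_year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))

    builder = _Builder(rng, t0)
    _BUILDERS[archetype](builder)

    gender = Gender(_draw_categorical(rng, demo["gender"]))
    record = PatientRecord(
        patient_id=f"P{index:06d}",
        birth_date=birth_date,
        gender=gender,
        race=_draw_categorical(rng, demo["race"]),
        ethnicity=_draw_categorical(rng, demo["ethnicity"]),
        marital_status=_draw_categorical(rng, demo["marital_status"]),
        insurance=_draw_categorical(rng, demo["insurance"]),
        region=_draw_categorical(rng, demo["region"]),
        urban_rural=_draw_categorical(rng, demo["urban_rural"]),
        diagnoses=sorted(builder.dx, key=lambda e: (e.date, e.code)),
        labs=[derive_lab(l, terminology)
              for l in sorted(builder.labs, key=lambda e: (e.date, e.test_name))],
        medications=[derive_med(m, terminology)
                     for m in sorted(builder.meds, key=lambda e: (e.date, e.drug_name))],
    )
    return record


def _assign_archetypes(spec: CohortSpec) -> List[Archetype]:
    if spec.counts is not None:
        order = [a for a in Archetype if spec.counts.get(a, 0) > 0]
        assigned: List[Archetype] = []
        for a in order:
            assigned.extend([a] * spec.counts[a])
        # deterministic shuffle so archetypes are interleaved across ids
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
        rng.shuffle(assigned)  # type: ignore[arg-type]
        return assigned
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    keys = sorted(spec.mixture, key=lambda a: a.value)
    probs = np.array([spec.mixture[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=spec.n, p=probs)
    return [keys[i] for i in idx]


def generate_cohort(
    spec: CohortSpec, terminology: Optional[TerminologyConfig] = None
) -> Tuple[Cohort, Dict[str, bool]]:
    """Generate exactly ``spec.n`` patients plus their gold-standard labels.

    Identical seed and spec yield byte-identical output; each patient is
    generated from its own seed substream, so changing the mixture does not
    perturb unrelated patients.
    """
    if terminology is None:
        terminology = default_terminology()
    archetypes = _assign_archetypes(spec)
    patients: List[PatientRecord] = []
    gold: Dict[str, bool] = {}
    for i, arch in enumerate(archetypes):
        p = _make_patient(i, arch, spec, terminology)
        patients.append(p)
        gold[p.patient_id] = ARCHETYPE_GOLD[arch]
    logger.info("generate_cohort: n=%d seed=%d archetypes=%d kinds",
                spec.n, spec.seed, len(set(archetypes)))
    cohort = Cohort(
        patients=patients,
        provenance=f"synthetic(seed={spec.seed})",
        terminology_version=terminology.version,
    )
    return cohort, gold


def archetype_assignment(spec: CohortSpec) -> Dict[str, Archetype]:
    """Map of patient_id -> archetype for a spec (same assignment as generate_cohort)."""
    return {f"P{i:06d}": a for i, a in enumerate(_assign_archetypes(spec))}
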