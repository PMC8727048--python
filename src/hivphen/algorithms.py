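"""The five rule-based HIV phenotyping classifiers.

All five consume the same normalized :class:`~hivphen.data_model.PatientRecord`
and emit a :class:`PhenotypeDecision` with a full evidence trail:

``FULTZ_ICD_ONLY``
    Claims-style: >=2 outpatient HIV ICD codes on distinct dates, or >=1
    inpatient HIV ICD code.
``PAUL_LAB``
    Testing-guideline cascade: positive screening followed by positive
    confirmatory test; otherwise viral load above threshold; otherwise any
    antiretroviral prescription.
``PAUL_ICD``
    ICD entry point (HIV code present) confirmed by a positive confirmatory
    test, a viral load above threshold, or an antiretroviral prescription.
``KRAMER_CRITERIA``
    At least 2 of 3: (1) HIV ICD code; (2) positive screening/confirmatory
    test, or any viral-load or CD4 measurement regardless of result;
    (3) any antiretroviral prescription.
``HIV_PHEN``
    At least 1 of 3, ignoring ICD codes entirely: positive confirmatory
    test; viral load above threshold (default 1000 copies/mL); or an
    antiretroviral regimen sufficient to treat (not merely prevent) HIV —
    a history consisting only of hepatitis-B/PrEP-capable agents does not
    qualify on its own.

Advisory flags (never label-changing): ``PEP_SUSPECT`` marks a single short
full regimen consistent with post-exposure prophylaxis;
``SAME_DAY_ARV_NEG_SCREEN`` marks an antiretroviral start on the same day as
a screening test that came back negative; ``NO_ICD_NO_POS_SCREEN`` marks
HIV-Phen positives invisible to ICD- or screening-based entry points.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import List, Optional, Tuple

import pandas as pd

from .data_model import Cohort, PatientRecord, Setting
from .terminology import (
    DrugClass,
    LabCategory,
    Qualitative,
    RegimenClass,
    TerminologyConfig,
    default_terminology,
    regimen_class,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Algorithm",
    "AlgorithmConfig",
    "PhenotypeDecision",
    "prefilter_candidates",
    "classify_fultz",
    "classify_paul_lab",
    "classify_paul_icd",
    "classify_kramer",
    "classify_hiv_phen",
    "run_algorithm",
    "decisions_frame",
    "write_decisions",
]


class Algorithm(str, Enum):
    FULTZ_ICD_ONLY = "FULTZ_ICD_ONLY"
    PAUL_LAB = "PAUL_LAB"
    PAUL_ICD = "PAUL_ICD"
    KRAMER_CRITERIA = "KRAMER_CRITERIA"
    HIV_PHEN = "HIV_PHEN"


# criterion tags
CONFIRMATORY_POS = "CONFIRMATORY_POS"
VL_GT_THRESHOLD = "VL_GT_THRESHOLD"
ARV_TREATMENT = "ARV_TREATMENT"
ARV_ANY = "ARV_ANY"
ICD_HIV = "ICD_HIV"
OUTPATIENT_ICD_2PLUS = "OUTPATIENT_ICD_2PLUS"
INPATIENT_ICD = "INPATIENT_ICD"
KRAMER_C1_ICD = "KRAMER_C1_ICD"
KRAMER_C2_LAB = "KRAMER_C2_LAB"
KRAMER_C3_ARV = "KRAMER_C3_ARV"

# advisory flags
PEP_SUSPECT = "PEP_SUSPECT"
SAME_DAY_ARV_NEG_SCREEN = "SAME_DAY_ARV_NEG_SCREEN"
NO_ICD_NO_POS_SCREEN = "NO_ICD_NO_POS_SCREEN"

HIV_PHEN_CRITERIA = frozenset({CONFIRMATORY_POS, VL_GT_THRESHOLD, ARV_TREATMENT})


@dataclass
class AlgorithmConfig:
    """Shared knobs for all classifiers.

    ``vl_threshold`` is the copies/mL cut-off above which a viral load
    counts as diagnostic evidence (default 1000, chosen to span the
    historical change in assay detection limits of 400 -> 48 -> 20).
    ``kramer_icd9_only`` restores the original ICD-9-only first criterion
    of the 2-of-3 baseline.
    """

    vl_threshold: float = 1000.0
    terminology: Optional[TerminologyConfig] = None
    prefilter: bool = True
    hiv_code_set: str = "hiv"
    kramer_icd9_only: bool = False

    def __post_init__(self) -> None:
        if self.vl_threshold <= 0:
            raise ValueError("vl_threshold must be positive")
        if self.terminology is None:
            self.terminology = default_terminology()


@dataclass(frozen=True)
class PhenotypeDecision:
    patient_id: str
    algorithm: Algorithm
    label: str  # "POSITIVE" | "NEGATIVE"
    criteria_met: frozenset
    evidence: Tuple[Tuple[str, str], ...]  # (event reference, role)
    flags: frozenset = frozenset()

    @property
    def positive(self) -> bool:
        return self.label == "POSITIVE"


class _Features:
    """Evidence-bearing facts shared by all five rules, with event references."""

    def __init__(self, p: PatientRecord, cfg: AlgorithmConfig):
        term = cfg.terminology
        hiv_set = term.code_set(cfg.hiv_code_set)
        self.hiv_icd: List[Tuple[str, object]] = []
        for i, d in enumerate(p.diagnoses):
            if hiv_set.matches(d.code, d.system):
                self.hiv_icd.append((f"dx:{i}", d))
        self.outpatient_dates = sorted(
            {d.date for _, d in self.hiv_icd if d.setting is Setting.OUTPATIENT}
        )
        self.inpatient = [(r, d) for r, d in self.hiv_icd if d.setting is Setting.INPATIENT]

        self.screen_pos: List[str] = []
        self.screen_neg_dates: List[dt.date] = []
        self.confirm_pos: List[str] = []
        self.vl_measured: List[str] = []
        self.vl_exceeding: List[Tuple[str, float]] = []
        self.cd4_measured: List[str] = []
        for i, l in enumerate(p.labs):
            ref = f"lab:{i}"
            interp = l.interpretation
            if interp is None or not interp.usable:
                continue
            if l.category is LabCategory.SCREENING:
                if interp.qualitative is Qualitative.POSITIVE:
                    self.screen_pos.append(ref)
                elif interp.qualitative is Qualitative.NEGATIVE:
                    self.screen_neg_dates.append(l.date)
            elif l.category is LabCategory.CONFIRMATORY:
                if interp.qualitative is Qualitative.POSITIVE:
                    self.confirm_pos.append(ref)
            elif l.category is LabCategory.VIRAL_LOAD:
                self.vl_measured.append(ref)
                if interp.exceeds(cfg.vl_threshold):
                    self.vl_exceeding.append((ref, interp.numeric_value))
            elif l.category is LabCategory.CD4:
                self.cd4_measured.append(ref)

        self.arv_events: List[Tuple[str, object]] = []
        self.all_arv_ingredients: set = set()
        for i, m in enumerate(p.medications):
            classes = {term.med_catalog.classify(x) for x in m.ingredients}
            if classes & {DrugClass.ARV_CORE, DrugClass.ARV_AMBIGUOUS}:
                self.arv_events.append((f"med:{i}", m))
                self.all_arv_ingredients |= {
                    x
                    for x in m.ingredients
                    if term.med_catalog.classify(x) is not DrugClass.NON_ARV
                }
        self.regimen = regimen_class(self.all_arv_ingredients, term.med_catalog)

    def advisory_flags(self) -> set:
        flags = set()
        if self.regimen is RegimenClass.TREATMENT_SUFFICIENT and self.arv_events:
            # single short episode: coverage from first fill to last fill + supply
            supplies = [m.days_supply for _, m in self.arv_events]
            if all(s is not None for s in supplies):
                start = min(m.date for _, m in self.arv_events)
                end = max(m.date + dt.timedelta(days=m.days_supply) for _, m in self.arv_events)
                if (end - start).days <= 35:
                    flags.add(PEP_SUSPECT)
        arv_dates = {m.date for _, m in self.arv_events}
        if arv_dates & set(self.screen_neg_dates):
            flags.add(SAME_DAY_ARV_NEG_SCREEN)
        return flags


def prefilter_candidates(cohort: Cohort, cfg: AlgorithmConfig) -> Cohort:
    """Candidate funnel: any HIV ICD code, any HIV-related lab event
    regardless of result, or any antiretroviral medication.

    A logical superset of every algorithm's positive set.
    """
    term = cfg.terminology
    hiv_set = term.code_set(cfg.hiv_code_set)
    kept = []
    for p in cohort.patients:
        has_icd = any(hiv_set.matches(d.code, d.system) for d in p.diagnoses)
        has_lab = any(l.category is not LabCategory.OTHER for l in p.labs)
        has_arv = any(
            term.med_catalog.classify(x) is not DrugClass.NON_ARV
            for m in p.medications
            for x in m.ingredients
        )
        if has_icd or has_lab or has_arv:
            kept.append(p)
    logger.info("prefilter: %d of %d patients retained", len(kept), len(cohort))
    return Cohort(
        patients=kept,
        provenance=cohort.provenance,
        terminology_version=cohort.terminology_version,
    )


def _decision(
    p: PatientRecord,
    algorithm: Algorithm,
    positive: bool,
    criteria: dict,
    flags: set = frozenset(),
) -> PhenotypeDecision:
    evidence = tuple((ref, tag) for tag, refs in criteria.items() for ref in refs)
    return PhenotypeDecision(
        patient_id=p.patient_id,
        algorithm=algorithm,
        label="POSITIVE" if positive else "NEGATIVE",
        criteria_met=frozenset(criteria),
        evidence=evidence,
        flags=frozenset(flags),
    )


def classify_fultz(p: PatientRecord, cfg: AlgorithmConfig) -> PhenotypeDecision:
    """>=2 outpatient HIV ICD codes on distinct dates, or >=1 inpatient HIV ICD code."""
    f = _Features(p, cfg)
    criteria: dict = {}
    if len(f.outpatient_dates) >= 2:
        refs = [
            r for r, d in f.hiv_icd
            if d.setting is Setting.OUTPATIENT and d.date in f.outpatient_dates
        ]
        criteria[OUTPATIENT_ICD_2PLUS] = refs
    if f.inpatient:
        criteria[INPATIENT_ICD] = [r for r, _ in f.inpatient]
    return _decision(p, Algorithm.FULTZ_ICD_ONLY, bool(criteria), criteria)


def classify_paul_lab(p: PatientRecord, cfg: AlgorithmConfig) -> PhenotypeDecision:
    """Guideline cascade: screen+ then confirm+; else VL above threshold; else any ARV.

    The medication arm counts any antiretroviral prescription, with no
    regimen-sufficiency screen (faithful to the baseline as published).
    """
    f = _Features(p, cfg)
    criteria: dict = {}
    if f.screen_pos and f.confirm_pos:
        criteria[CONFIRMATORY_POS] = f.screen_pos + f.confirm_pos
    if f.vl_exceeding:
        criteria[VL_GT_THRESHOLD] = [r for r, _ in f.vl_exceeding]
    if f.arv_events:
        criteria[ARV_ANY] = [r for r, _ in f.arv_events]
    return _decision(p, Algorithm.PAUL_LAB, bool(criteria), criteria, f.advisory_flags())


def classify_paul_icd(p: PatientRecord, cfg: AlgorithmConfig) -> PhenotypeDecision:
    """HIV ICD entry point confirmed by confirm+ test, VL above threshold, or any ARV."""
    f = _Features(p, cfg)
    criteria: dict = {}
    if f.hiv_icd:
        criteria[ICD_HIV] = [r for r, _ in f.hiv_icd]
    confirmation = False
    if f.confirm_pos:
        criteria[CONFIRMATORY_POS] = list(f.confirm_pos)
        confirmation = True
    if f.vl_exceeding:
        criteria[VL_GT_THRESHOLD] = [r for r, _ in f.vl_exceeding]
        confirmation = True
    if f.arv_events:
        criteria[ARV_ANY] = [r for r, _ in f.arv_events]
        confirmation = True
    positive = bool(f.hiv_icd) and confirmation
    return _decision(p, Algorithm.PAUL_ICD, positive, criteria, f.advisory_flags())


def classify_kramer(p: PatientRecord, cfg: AlgorithmConfig) -> PhenotypeDecision:
    """2-of-3 criteria: HIV ICD code; positive screen/confirm or any VL/CD4
    measurement regardless of result; any ARV prescription."""
    f = _Features(p, cfg)
    criteria: dict = {}
    icd_refs = [
        r for r, d in f.hiv_icd
        if not (cfg.kramer_icd9_only and d.system.value != "ICD9")
    ]
    if icd_refs:
        criteria[KRAMER_C1_ICD] = icd_refs
    c2_refs = f.screen_pos + f.confirm_pos + f.vl_measured + f.cd4_measured
    if c2_refs:
        criteria[KRAMER_C2_LAB] = c2_refs
    if f.arv_events:
        criteria[KRAMER_C3_ARV] = [r for r, _ in f.arv_events]
    return _decision(
        p, Algorithm.KRAMER_CRITERIA, len(criteria) >= 2, criteria, f.advisory_flags()
    )


def classify_hiv_phen(p: PatientRecord, cfg: AlgorithmConfig) -> PhenotypeDecision:
    """1-of-3 criteria over labs and medications only; ICD codes are ignored.

    A positive confirmatory test, a viral load above ``cfg.vl_threshold``,
    or a treatment-sufficient antiretroviral regimen.  Regimens consisting
    only of hepatitis-B/PrEP-capable agents contribute nothing on their own.
    """
    f = _Features(p, cfg)
    criteria: dict = {}
    if f.confirm_pos:
        criteria[CONFIRMATORY_POS] = list(f.confirm_pos)
    if f.vl_exceeding:
        criteria[VL_GT_THRESHOLD] = [r for r, _ in f.vl_exceeding]
    if f.regimen is RegimenClass.TREATMENT_SUFFICIENT:
        criteria[ARV_TREATMENT] = [r for r, _ in f.arv_events]
    flags = f.advisory_flags()
    if not f.hiv_icd and not f.screen_pos:
        flags.add(NO_ICD_NO_POS_SCREEN)
    return _decision(p, Algorithm.HIV_PHEN, bool(criteria), criteria, flags)


_CLASSIFIERS = {
    Algorithm.FULTZ_ICD_ONLY: classify_fultz,
    Algorithm.PAUL_LAB: classify_paul_lab,
    Algorithm.PAUL_ICD: classify_paul_icd,
    Algorithm.KRAMER_CRITERIA: classify_kramer,
    Algorithm.HIV_PHEN: classify_hiv_phen,
}


def run_algorithm(
    cohort: Cohort, algorithm: Algorithm, cfg: Optional[AlgorithmConfig] = None
) -> List[PhenotypeDecision]:
    """One decision per patient; deterministic and order-independent."""
    if cfg is None:
        cfg = AlgorithmConfig()
    try:
        classify = _CLASSIFIERS[Algorithm(algorithm)]
    except (KeyError, ValueError):
        raise ValueError(f"unknown algorithm: {algorithm!r}") from None
    return [classify(p, cfg) for p in cohort.patients]


def decisions_frame(decisions: List[PhenotypeDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": d.patient_id,
                "algorithm": d.algorithm.value,
                "label": d.label,
                "criteria_met": ";".join(sorted(d.criteria_met)),
                "flags": ";".join(sorted(d.flags)),
                "n_evidence": len(d.evidence),
            }
            for d in decisions
        ],
        columns=["patient_id", "algorithm", "label", "criteria_met", "flags", "n_evidence"],
    )


def write_decisions(decisions: List[PhenotypeDecision], path: Path) -> None:
    decisions_frame(decisions).to_csv(Path(path), index=False)
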