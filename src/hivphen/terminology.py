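"""Diagnosis code sets, laboratory test catalogues and medication classification.

Every phenotyping classifier in this package consumes ICD codes, lab results
and medication records exclusively through the :class:`TerminologyConfig`
loaded here.  The shipped defaults (``hivphen/config/``) are clinically
standard HIV code lists, keyword-based lab-test patterns, and an
antiretroviral ingredient catalogue; they are explicit stand-ins meant to be
replaced by locally curated lists, because lab test names in particular are
not standardized across institutions.

Medication classes
------------------
``ARV_CORE``
    Antiretroviral agents whose prescription implies HIV *treatment*
    (anchor agents such as integrase inhibitors, NNRTIs, protease
    inhibitors, and the older NRTIs not used outside HIV care).
``ARV_AMBIGUOUS``
    Agents that are also used for hepatitis B therapy or for pre-exposure
    prophylaxis (tenofovir products, emtricitabine, lamivudine).  A patient
    whose entire antiretroviral history is a subset of this class is *not*
    treatment-sufficient on medication evidence alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

__all__ = [
    "CodeSystem",
    "MatchMode",
    "LabCategory",
    "Qualitative",
    "DrugClass",
    "RegimenClass",
    "CodeSet",
    "LabTestCatalog",
    "MedicationCatalog",
    "LabInterpretation",
    "TerminologyConfig",
    "TerminologyError",
    "CodeParseError",
    "normalize_code",
    "match_code",
    "classify_lab_test",
    "interpret_lab",
    "normalize_drug",
    "regimen_class",
    "load_terminology",
    "default_terminology",
    "save_terminology",
]


class TerminologyError(ValueError):
    """Malformed terminology configuration."""


class CodeParseError(ValueError):
    """A diagnosis code could not be normalized."""


class CodeSystem(str, Enum):
    ICD9 = "ICD9"
    ICD10 = "ICD10"


class MatchMode(str, Enum):
    EXACT = "EXACT"
    PREFIX = "PREFIX"


class LabCategory(str, Enum):
    SCREENING = "SCREENING"
    CONFIRMATORY = "CONFIRMATORY"
    VIRAL_LOAD = "VIRAL_LOAD"
    CD4 = "CD4"
    OTHER = "OTHER"


class Qualitative(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    INDETERMINATE = "INDETERMINATE"
    NOT_APPLICABLE = "NOT_APPLICABLE"


class DrugClass(str, Enum):
    ARV_CORE = "ARV_CORE"
    ARV_AMBIGUOUS = "ARV_AMBIGUOUS"
    NON_ARV = "NON_ARV"


class RegimenClass(str, Enum):
    TREATMENT_SUFFICIENT = "TREATMENT_SUFFICIENT"
    AMBIGUOUS_ONLY = "AMBIGUOUS_ONLY"
    NO_ARV = "NO_ARV"


def normalize_code(raw: str, system: CodeSystem) -> str:
    """Normalize a raw ICD code: strip whitespace, uppercase, remove dots.

    Idempotent; raises :class:`CodeParseError` on empty/garbage input.
    """
    if raw is None:
        raise CodeParseError("diagnosis code is missing")
    code = str(raw).strip().upper().replace(".", "")
    if not code or not re.fullmatch(r"[A-Z0-9]+", code):
        raise CodeParseError(f"unparseable {system.value} code: {raw!r}")
    return code


@dataclass(frozen=True)
class CodeSet:
    """A named set of normalized ICD codes with exact and prefix entries."""

    name: str
    exact: Mapping[CodeSystem, frozenset]
    prefix: Mapping[CodeSystem, tuple]

    def __post_init__(self) -> None:
        for table in (self.exact, self.prefix):
            for system, codes in table.items():
                for c in codes:
                    if not c or c != c.upper() or "." in c:
                        raise TerminologyError(
                            f"code set {self.name!r}: code {c!r} is not normalized"
                        )

    def matches(self, code: str, system: CodeSystem) -> bool:
        if code in self.exact.get(system, frozenset()):
            return True
        return any(code.startswith(p) for p in self.prefix.get(system, ()))


def match_code(code: str, system: CodeSystem, code_set: CodeSet) -> bool:
    """True iff a normalized ``code`` is in the set (exact or prefix match)."""
    return code_set.matches(code, system)


@dataclass(frozen=True)
class LabTestCatalog:
    """Ordered case-insensitive substring patterns mapping test names to categories.

    First match wins, so more specific patterns (confirmatory assay names,
    RNA/viral-load keywords) must precede the generic screening fallbacks.
    """

    entries: tuple  # of (pattern: str, category: LabCategory)

    def __post_init__(self) -> None:
        if not self.entries:
            raise TerminologyError("lab test catalog is empty")

    def categorize(self, test_name: str) -> LabCategory:
        name = " ".join(str(test_name).upper().split())
        for pattern, category in self.entries:
            if pattern in name:
                return category
        return LabCategory.OTHER


def classify_lab_test(test_name: str, catalog: LabTestCatalog) -> LabCategory:
    """Deterministic first-match category for a free-text lab test name."""
    return catalog.categorize(test_name)


def normalize_drug(name: str) -> str:
    return " ".join(str(name).lower().split())


@dataclass(frozen=True)
class MedicationCatalog:
    """Ingredient classification plus combination-product expansion."""

    ingredients: Mapping[str, DrugClass]
    combinations: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        for combo, parts in self.combinations.items():
            if len(parts) < 2:
                raise TerminologyError(
                    f"combination product {combo!r} must expand to >=2 ingredients"
                )

    def expand(self, drug_name: str) -> frozenset:
        """Expand a prescription name to its normalized ingredient set.

        Unknown drugs pass through as a singleton of their own normalized
        name (classified NON_ARV), keeping the pipeline robust to noisy
        formularies.
        """
        name = normalize_drug(drug_name)
        if name in self.combinations:
            return self.combinations[name]
        return frozenset({name})

    def classify(self, ingredient: str) -> DrugClass:
        return self.ingredients.get(normalize_drug(ingredient), DrugClass.NON_ARV)


def regimen_class(patient_meds: Iterable[str], catalog: MedicationCatalog) -> RegimenClass:
    """Classify a patient's full antiretroviral ingredient history.

    ``TREATMENT_SUFFICIENT`` needs at least one core (anchor) agent ever
    prescribed; a history consisting only of hepatitis-B/PrEP-capable agents
    is ``AMBIGUOUS_ONLY`` and does not by itself support an HIV diagnosis.
    Evaluated over the entire record, not per-date windows.
    """
    classes = {catalog.classify(m) for m in patient_meds}
    if DrugClass.ARV_CORE in classes:
        return RegimenClass.TREATMENT_SUFFICIENT
    if DrugClass.ARV_AMBIGUOUS in classes:
        return RegimenClass.AMBIGUOUS_ONLY
    return RegimenClass.NO_ARV


@dataclass(frozen=True)
class LabInterpretation:
    """Machine-readable interpretation of one lab result.

    For viral loads, ``numeric_value`` is in copies/mL; censored results
    ("<N", "NOT DETECTED") carry ``detectable=False`` and, for "<N", the
    censoring bound in ``numeric_value``.  ``open_upper`` marks ">N"
    results, which exceed any threshold strictly below N.
    """

    category: LabCategory
    qualitative: Qualitative = Qualitative.NOT_APPLICABLE
    numeric_value: Optional[float] = None
    detectable: Optional[bool] = None
    open_upper: bool = False
    usable: bool = True

    def exceeds(self, threshold: float) -> bool:
        """Does this result demonstrate a value strictly above ``threshold``?

        Censored results never do: "<N" guarantees nothing above the bound
        for thresholds >= N, and below the bound the true value is unknown,
        so no credit is given there either (conservative).
        """
        if not self.usable or self.category is not LabCategory.VIRAL_LOAD:
            return False
        if self.open_upper and self.numeric_value is not None:
            return threshold < self.numeric_value
        if self.detectable is False:
            return False
        if self.numeric_value is not None:
            return self.numeric_value > threshold
        return False


_NUMBER_RE = re.compile(r"^\d+(\.\d+)?$")


def _parse_number(text: str) -> Optional[float]:
    cleaned = text.replace(",", "").replace(" ", "")
    if _NUMBER_RE.fullmatch(cleaned):
        return float(cleaned)
    return None


def interpret_lab(
    category: LabCategory,
    raw_value: str,
    units: Optional[str] = None,
    config: Optional["TerminologyConfig"] = None,
) -> LabInterpretation:
    """Parse a raw result string into a :class:`LabInterpretation`.

    Qualitative results (screening/confirmatory) go through the config's
    synonym table; viral loads are parsed tolerantly (thousands separators,
    "<N"/">N" bounds, undetectable synonyms).  Unparseable values yield an
    interpretation flagged ``usable=False`` that contributes to no criterion.
    """
    cfg = config if config is not None else default_terminology()
    if category in (LabCategory.OTHER,):
        return LabInterpretation(category=category, usable=False)
    text = " ".join(str(raw_value).upper().split())
    if category in (LabCategory.SCREENING, LabCategory.CONFIRMATORY):
        qual = cfg.qualitative_synonyms.get(text)
        if qual is None:
            return LabInterpretation(category=category, usable=False)
        return LabInterpretation(category=category, qualitative=qual)
    if category is LabCategory.VIRAL_LOAD:
        if text in cfg.undetectable_synonyms:
            return LabInterpretation(category=category, detectable=False)
        if text.startswith("<"):
            bound = _parse_number(text[1:])
            if bound is None:
                return LabInterpretation(category=category, usable=False)
            return LabInterpretation(
                category=category, numeric_value=bound, detectable=False
            )
        if text.startswith(">"):
            bound = _parse_number(text[1:])
            if bound is None:
                return LabInterpretation(category=category, usable=False)
            return LabInterpretation(
                category=category, numeric_value=bound, detectable=True, open_upper=True
            )
        value = _parse_number(text)
        if value is None:
            return LabInterpretation(category=category, usable=False)
        return LabInterpretation(
            category=category, numeric_value=value, detectable=value > 0
        )
    # CD4: numeric cells/uL
    value = _parse_number(text)
    if value is None:
        return LabInterpretation(category=category, usable=False)
    return LabInterpretation(category=category, numeric_value=value)


@dataclass(frozen=True)
class TerminologyConfig:
    """All code sets, catalogues and synonym tables in force for a run."""

    version: str
    code_sets: Mapping[str, CodeSet]
    lab_catalog: LabTestCatalog
    med_catalog: MedicationCatalog
    qualitative_synonyms: Mapping[str, Qualitative]
    undetectable_synonyms: frozenset
    source: Optional[Path] = None
    # raw table rows preserved for byte-identical re-serialization
    _raw_tables: Mapping[str, str] = field(default_factory=dict, repr=False)

    def code_set(self, name: str) -> CodeSet:
        try:
            return self.code_sets[name]
        except KeyError:
            raise TerminologyError(f"no code set named {name!r}") from None


def _read_tsv(text: str, path_label: str, expected: tuple) -> list:
    lines = text.rstrip("\n").split("\n")
    header = tuple(lines[0].split("\t"))
    if header[: len(expected)] != expected:
        raise TerminologyError(
            f"{path_label}: expected columns {expected}, found {header}"
        )
    rows = []
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        cells += [""] * (len(expected) - len(cells))
        rows.append(cells)
    return rows


def _build_code_sets(rows: list) -> dict:
    exact: dict = {}
    prefix: dict = {}
    for set_name, system_s, code, mode_s in rows:
        system = CodeSystem(system_s)
        mode = MatchMode(mode_s)
        code_n = normalize_code(code, system)
        target = exact if mode is MatchMode.EXACT else prefix
        target.setdefault(set_name, {}).setdefault(system, set()).add(code_n)
    names = set(exact) | set(prefix)
    return {
        name: CodeSet(
            name=name,
            exact={s: frozenset(c) for s, c in exact.get(name, {}).items()},
            prefix={s: tuple(sorted(c)) for s, c in prefix.get(name, {}).items()},
        )
        for name in names
    }


def load_terminology(path: Optional[Path] = None) -> "TerminologyConfig":
    """Load a terminology config from a YAML manifest (default: shipped config)."""
    if path is None:
        base = resources.files("hivphen") / "config"
        manifest_text = (base / "terminology.yaml").read_text(encoding="utf-8")
        read = lambda name: (base / name).read_text(encoding="utf-8")  # noqa: E731
        source = None
    else:
        path = Path(path)
        manifest_text = path.read_text(encoding="utf-8")
        read = lambda name: (path.parent / name).read_text(encoding="utf-8")  # noqa: E731
        source = path
    manifest = yaml.safe_load(manifest_text)
    tables = manifest["tables"]

    icd_text = read(tables["icd_codes"])
    lab_text = read(tables["lab_tests"])
    med_text = read(tables["medications"])

    code_sets = _build_code_sets(
        _read_tsv(icd_text, tables["icd_codes"], ("set_name", "system", "code", "match_mode"))
    )
    lab_rows = _read_tsv(lab_text, tables["lab_tests"], ("pattern", "category"))
    lab_catalog = LabTestCatalog(
        entries=tuple((p.upper(), LabCategory(c)) for p, c in lab_rows)
    )
    med_rows = _read_tsv(
        med_text, tables["medications"], ("ingredient", "class", "combo_expansion")
    )
    ingredients: dict = {}
    combinations: dict = {}
    for name, cls, expansion in med_rows:
        name_n = normalize_drug(name)
        if expansion:
            parts = frozenset(normalize_drug(x) for x in expansion.split(";") if x.strip())
            combinations[name_n] = parts
        else:
            ingredients[name_n] = DrugClass(cls)
    core = {k for k, v in ingredients.items() if v is DrugClass.ARV_CORE}
    ambiguous = {k for k, v in ingredients.items() if v is DrugClass.ARV_AMBIGUOUS}
    if core & ambiguous:
        raise TerminologyError("ARV_CORE and ARV_AMBIGUOUS overlap in medication table")

    synonyms: dict = {}
    for label, words in manifest["qualitative_synonyms"].items():
        qual = Qualitative(label)
        for w in words:
            key = " ".join(str(w).upper().split())
            if key in synonyms and synonyms[key] is not qual:
                raise TerminologyError(f"synonym {key!r} maps to two qualitative values")
            synonyms[key] = qual
    undetectable = frozenset(
        " ".join(str(w).upper().split()) for w in manifest["undetectable_synonyms"]
    )

    return TerminologyConfig(
        version=str(manifest.get("version", "unversioned")),
        code_sets=code_sets,
        lab_catalog=lab_catalog,
        med_catalog=MedicationCatalog(ingredients=ingredients, combinations=combinations),
        qualitative_synonyms=synonyms,
        undetectable_synonyms=undetectable,
        source=source,
        _raw_tables={
            tables["icd_codes"]: icd_text,
            tables["lab_tests"]: lab_text,
            tables["medications"]: med_text,
        },
    )


@lru_cache(maxsize=1)
def default_terminology() -> "TerminologyConfig":
    """The shipped default config, loaded once per process."""
    return load_terminology()


def save_terminology(config: TerminologyConfig, out_dir: Path) -> None:
    """Write the config's tables back out byte-identically (round-trip contract)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, text in config._raw_tables.items():
        (out_dir / name).write_text(text, encoding="utf-8")
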