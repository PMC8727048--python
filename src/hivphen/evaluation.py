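"""Validation metrics, algorithm comparisons and sensitivity analyses.

Implements the full evaluation workflow for a phenotyping run: confusion
counts against a chart-review (or synthetic gold-standard) label set, the
standard diagnostic metrics (sensitivity, specificity, PPV, NPV, accuracy)
with half-up rounding at a configurable precision, Cochran sample-size
computation for 1:1 case-control chart-review subsampling, the three-way
criterion Venn breakdown of HIV-Phen positives, pairwise algorithm overlap,
viral-load-threshold sensitivity scans, and descriptive demographic
comparison against surveillance reference distributions.

Undefined ratios (zero denominators) are reported as absent (``None``),
never as zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .algorithms import (
    Algorithm,
    AlgorithmConfig,
    ARV_TREATMENT,
    CONFIRMATORY_POS,
    NO_ICD_NO_POS_SCREEN,
    PhenotypeDecision,
    VL_GT_THRESHOLD,
    run_algorithm,
)
from .data_model import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "EvaluationReport",
    "confusion",
    "metrics",
    "compare_algorithms",
    "sample_for_review",
    "criterion_venn",
    "overlap",
    "threshold_scan",
    "percent_increase",
    "demographic_comparison",
    "round_half_up",
]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.955 -> 0.96), as printed metric tables round."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Chart/gold status crossed with algorithm label (tp, fn, fp, tn)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricSet:
    """The five diagnostic metrics, rounded half-up to ``decimals`` places.

    Raw (unrounded) values are kept alongside; a metric whose denominator
    is zero is ``None``.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]
    decimals: int = 2
    raw: Optional[Mapping[str, Optional[float]]] = None


def confusion(
    decisions: Sequence[PhenotypeDecision], gold: Mapping[str, bool]
) -> ConfusionCounts:
    """Cross-tabulate algorithm labels against the gold standard."""
    missing = [d.patient_id for d in decisions if d.patient_id not in gold]
    if missing:
        raise ValueError(f"patients missing from gold standard: {sorted(missing)[:10]}")
    tp = fn = fp = tn = 0
    for d in decisions:
        truth = gold[d.patient_id]
        if truth and d.positive:
            tp += 1
        elif truth:
            fn += 1
        elif d.positive:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts, decimals: int = 2) -> MetricSet:
    """Sensitivity, specificity, PPV, NPV, accuracy with half-up rounding."""
    if c.total <= 0:
        raise ValueError("confusion counts are empty")
    raw = {
        "sensitivity": _ratio(c.tp, c.tp + c.fn),
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "ppv": _ratio(c.tp, c.tp + c.fp),
        "npv": _ratio(c.tn, c.tn + c.fn),
        "accuracy": _ratio(c.tp + c.tn, c.total),
    }
    rounded = {
        k: (None if v is None else round_half_up(v, decimals)) for k, v in raw.items()
    }
    return MetricSet(decimals=decimals, raw=raw, **rounded)


@dataclass
class EvaluationReport:
    """One row of confusion counts + metrics per algorithm evaluated."""

    rows: List[Tuple[Algorithm, ConfusionCounts, MetricSet]]
    provenance: str = ""
    vl_threshold: float = 1000.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "algorithm": alg.value,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "ppv": m.ppv,
                    "npv": m.npv,
                    "accuracy": m.accuracy,
                    "tp": c.tp,
                    "fn": c.fn,
                    "fp": c.fp,
                    "tn": c.tn,
                }
                for alg, c, m in self.rows
            ]
        )


def compare_algorithms(
    cohort: Cohort,
    gold: Mapping[str, bool],
    algorithms: Sequence[Algorithm],
    cfg: Optional[AlgorithmConfig] = None,
) -> EvaluationReport:
    """Run each algorithm over the cohort and tabulate its metrics."""
    if not algorithms:
        raise ValueError("at least one algorithm is required")
    if cfg is None:
        cfg = AlgorithmConfig()
    rows = []
    for alg in algorithms:
        decisions = run_algorithm(cohort, alg, cfg)
        c = confusion(decisions, gold)
        rows.append((Algorithm(alg), c, metrics(c)))
    return EvaluationReport(
        rows=rows, provenance=cohort.provenance, vl_threshold=cfg.vl_threshold
    )


def cochran_sample_size(confidence: float = 0.95, margin: float = 0.05) -> int:
    """Cochran sample size with p = 0.5 and no finite-population correction."""
    z = stats.norm.ppf(1 - (1 - confidence) / 2)
    return math.ceil(z * z * 0.25 / (margin * margin))


def sample_for_review(
    decisions: Sequence[PhenotypeDecision],
    ratio: Tuple[int, int] = (1, 1),
    confidence: float = 0.95,
    margin: float = 0.05,
    seed: int = 0,
    n_total: Optional[int] = None,
) -> List[str]:
    """Seeded case-control subsample for manual chart review.

    Total size is the Cochran estimate (385 at 95%/5%) unless ``n_total``
    is given, split between algorithm-positive cases and algorithm-negative
    controls in ``ratio`` (cases get the rounding remainder).  Requests
    exceeding the available class sizes are capped with a warning.
    """
    cases = sorted(d.patient_id for d in decisions if d.positive)
    controls = sorted(d.patient_id for d in decisions if not d.positive)
    if not cases or not controls:
        raise ValueError("both predicted classes must be non-empty for case-control sampling")
    total = n_total if n_total is not None else cochran_sample_size(confidence, margin)
    r_cases, r_controls = ratio
    n_cases = math.ceil(total * r_cases / (r_cases + r_controls))
    n_controls = total - n_cases
    if n_cases > len(cases):
        logger.warning("sample_for_review: only %d cases available (wanted %d)",
                       len(cases), n_cases)
        n_cases = len(cases)
    if n_controls > len(controls):
        logger.warning("sample_for_review: only %d controls available (wanted %d)",
                       len(controls), n_controls)
        n_controls = len(controls)
    rng = np.random.default_rng(seed)
    picked = list(rng.choice(cases, size=n_cases, replace=False)) + list(
        rng.choice(controls, size=n_controls, replace=False)
    )
    return [str(x) for x in picked]


_VENN_CRITERIA = (CONFIRMATORY_POS, VL_GT_THRESHOLD, ARV_TREATMENT)


def criterion_venn(decisions: Sequence[PhenotypeDecision]) -> Dict[str, object]:
    """Three-way Venn of HIV-Phen positives over its criteria, plus, per
    criterion, how many qualifying patients lack both an HIV ICD code and a
    positive screening test (the patients invisible to code/screen-based
    algorithms).
    """
    for d in decisions:
        if d.algorithm is not Algorithm.HIV_PHEN:
            raise ValueError("criterion_venn requires HIV_PHEN decisions")
    positives = [d for d in decisions if d.positive]
    regions: Dict[frozenset, int] = {}
    for r in range(1, 4):
        for combo in combinations(_VENN_CRITERIA, r):
            regions[frozenset(combo)] = 0
    for d in positives:
        key = frozenset(d.criteria_met & set(_VENN_CRITERIA))
        regions[key] += 1
    per_criterion = {}
    for crit in _VENN_CRITERIA:
        meeting = [d for d in positives if crit in d.criteria_met]
        flagged = [d for d in meeting if NO_ICD_NO_POS_SCREEN in d.flags]
        per_criterion[crit] = {
            "count": len(meeting),
            "share_of_positives": _ratio(len(meeting), len(positives)),
            "flagged_no_icd_no_pos_screen": len(flagged),
            "flagged_share": _ratio(len(flagged), len(meeting)),
        }
    return {
        "total_positive": len(positives),
        "regions": {"&".join(sorted(k)): v for k, v in regions.items()},
        "per_criterion": per_criterion,
    }


def overlap(
    decisions_a: Sequence[PhenotypeDecision], decisions_b: Sequence[PhenotypeDecision]
) -> Tuple[int, int, int, int]:
    """Positive-set overlap between two algorithms on the same patient universe:
    (only_a, only_b, both, neither)."""
    a = {d.patient_id: d.positive for d in decisions_a}
    b = {d.patient_id: d.positive for d in decisions_b}
    if set(a) != set(b):
        raise ValueError("decision lists cover different patient universes")
    only_a = only_b = both = neither = 0
    for pid in a:
        pa, pb = a[pid], b[pid]
        if pa and pb:
            both += 1
        elif pa:
            only_a += 1
        elif pb:
            only_b += 1
        else:
            neither += 1
    return only_a, only_b, both, neither


def threshold_scan(
    cohort: Cohort,
    thresholds: Sequence[float],
    cfg: Optional[AlgorithmConfig] = None,
) -> pd.DataFrame:
    """HIV-Phen positive counts at each viral-load threshold, with percent
    change relative to the reference threshold in ``cfg`` (default 1000)."""
    if cfg is None:
        cfg = AlgorithmConfig()
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    ref_cfg = AlgorithmConfig(
        vl_threshold=cfg.vl_threshold, terminology=cfg.terminology,
        hiv_code_set=cfg.hiv_code_set,
    )
    ref_count = sum(d.positive for d in run_algorithm(cohort, Algorithm.HIV_PHEN, ref_cfg))
    rows = []
    for t in thresholds:
        scan_cfg = AlgorithmConfig(
            vl_threshold=float(t), terminology=cfg.terminology,
            hiv_code_set=cfg.hiv_code_set,
        )
        count = sum(d.positive for d in run_algorithm(cohort, Algorithm.HIV_PHEN, scan_cfg))
        rows.append(
            {
                "threshold": float(t),
                "n_positive": int(count),
                "pct_change_vs_reference": (
                    round_half_up((count - ref_count) / ref_count * 100.0)
                    if ref_count > 0 else None
                ),
            }
        )
    return pd.DataFrame(rows)


def percent_increase(a: int, b: int) -> Optional[float]:
    """(a - b) / b * 100, rounded half-up to 2 decimals; absent when b = 0."""
    if b == 0:
        return None
    return round_half_up((a - b) / b * 100.0, 2)


def demographic_comparison(
    values: Iterable[str], reference: Mapping[str, float]
) -> pd.DataFrame:
    """Descriptive side-by-side category proportions: cohort vs a reference
    distribution (no hypothesis test).  Cohort categories missing from the
    reference are pooled into OTHER with a warning.
    """
    values = list(values)
    if not values:
        raise ValueError("empty positive set: nothing to compare")
    ref = {str(k).upper(): float(v) for k, v in reference.items()}
    total_ref = sum(ref.values())
    counts: Dict[str, int] = {}
    for v in values:
        key = str(v).upper()
        if key not in ref:
            if key != "OTHER":
                logger.warning("demographic_comparison: category %r not in reference, "
                               "pooled into OTHER", v)
            key = "OTHER"
        counts[key] = counts.get(key, 0) + 1
    categories = sorted(set(ref) | set(counts))
    n = len(values)
    return pd.DataFrame(
        [
            {
                "category": cat,
                "cohort_count": counts.get(cat, 0),
                "cohort_proportion": counts.get(cat, 0) / n,
                "reference_proportion": ref.get(cat, 0.0) / total_ref if total_ref else 0.0,
            }
            for cat in categories
        ]
    )
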