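import dataclasses

import numpy as np
import pytest

from hivphen.algorithms import (
    Algorithm,
    AlgorithmConfig,
    NO_ICD_NO_POS_SCREEN,
    PEP_SUSPECT,
    SAME_DAY_ARV_NEG_SCREEN,
    classify_fultz,
    classify_hiv_phen,
    classify_kramer,
    classify_paul_icd,
    classify_paul_lab,
    prefilter_candidates,
    run_algorithm,
)
from hivphen.data_model import Cohort

from _oracle import oracle_labels, random_record
from conftest import make_record


class TestFultz:
    def test_two_outpatient_codes_distinct_dates(self, cfg):
        p = make_record(dx=[(0, "B20", "OUTPATIENT"), (30, "B20", "OUTPATIENT")])
        assert classify_fultz(p, cfg).positive

    def test_one_inpatient_code(self, cfg):
        p = make_record(dx=[(0, "B20", "INPATIENT")])
        assert classify_fultz(p, cfg).positive

    def test_single_outpatient_code_insufficient(self, cfg):
        p = make_record(dx=[(0, "B20", "OUTPATIENT")])
        assert not classify_fultz(p, cfg).positive

    def test_same_day_duplicate_outpatient_codes_insufficient(self, cfg):
        # duplicate same-day billing rows must not qualify
        p = make_record(dx=[(0, "B20", "OUTPATIENT"), (0, "Z21", "OUTPATIENT")])
        assert not classify_fultz(p, cfg).positive


class TestPaulLab:
    def test_screen_then_confirm_positive(self, cfg):
        p = make_record(
            labs=[(0, "HIV ANTIBODY SCREEN", "REACTIVE"),
                  (7, "HIV 1 WESTERN BLOT", "POSITIVE")]
        )
        d = classify_paul_lab(p, cfg)
        assert d.positive and "CONFIRMATORY_POS" in d.criteria_met

    def test_vl_path_without_screening(self, cfg):
        p = make_record(labs=[(0, "HIV 1 RNA QUANT PCR", "5000")])
        assert classify_paul_lab(p, cfg).positive

    def test_cascade_all_negative(self, cfg):
        p = make_record(
            labs=[(0, "HIV ANTIBODY SCREEN", "REACTIVE"),
                  (7, "HIV 1 WESTERN BLOT", "NEGATIVE"),
                  (14, "HIV 1 RNA QUANT PCR", "NOT DETECTED")]
        )
        assert not classify_paul_lab(p, cfg).positive

    def test_confirmatory_without_screening_is_not_a_path(self, cfg):
        # the cascade enters via a positive screen; a lone confirm+ does not qualify
        p = make_record(labs=[(0, "HIV 1 WESTERN BLOT", "POSITIVE")])
        assert not classify_paul_lab(p, cfg).positive


class TestPaulIcd:
    def test_icd_plus_high_vl(self, cfg):
        p = make_record(dx=[(0, "B20", "OUTPATIENT")],
                        labs=[(0, "HIV 1 RNA QUANT PCR", "2000")])
        assert classify_paul_icd(p, cfg).positive

    def test_icd_without_confirmation(self, cfg):
        p = make_record(dx=[(0, "B20", "OUTPATIENT")])
        assert not classify_paul_icd(p, cfg).positive

    def test_high_vl_without_icd_entry(self, cfg):
        p = make_record(labs=[(0, "HIV 1 RNA QUANT PCR", "2000")])
        assert not classify_paul_icd(p, cfg).positive


class TestKramer:
    def test_icd_plus_any_cd4_measurement(self, cfg):
        p = make_record(dx=[(0, "B20", "OUTPATIENT")],
                        labs=[(0, "ABSOLUTE CD4 COUNT", "900")])
        assert classify_kramer(p, cfg).positive

    def test_single_criterion_insufficient(self, cfg):
        p = make_record(meds=[(0, "biktarvy")])
        assert not classify_kramer(p, cfg).positive

    def test_empty_record_negative(self, cfg):
        assert not classify_kramer(make_record(), cfg).positive

    def test_icd9_only_mode_ignores_icd10_codes(self, term):
        strict = AlgorithmConfig(terminology=term, kramer_icd9_only=True)
        p = make_record(dx=[(0, "B20", "OUTPATIENT")],
                        labs=[(0, "ABSOLUTE CD4 COUNT", "900")])
        assert not classify_kramer(p, strict).positive


class TestHivPhen:
    def test_single_high_vl_positive_with_flag(self, cfg):
        p = make_record(labs=[(0, "HIV 1 RNA QUANT PCR", "1500")])
        d = classify_hiv_phen(p, cfg)
        assert d.positive
        assert NO_ICD_NO_POS_SCREEN in d.flags

    def test_prep_pattern_negative(self, cfg):
        p = make_record(
            labs=[(0, "HIV ANTIBODY SCREEN", "NONREACTIVE")],
            meds=[(0, "truvada"), (30, "truvada")],
        )
        assert not classify_hiv_phen(p, cfg).positive

    def test_vl_below_threshold_negative(self, cfg):
        p = make_record(labs=[(0, "HIV 1 RNA QUANT PCR", "800")])
        assert not classify_hiv_phen(p, cfg).positive

    def test_vl_exactly_at_threshold_negative(self, cfg):
        # criterion is strictly greater-than
        p = make_record(labs=[(0, "HIV 1 RNA QUANT PCR", "1000")])
        assert not classify_hiv_phen(p, cfg).positive

    def test_pep_advisory_flags_do_not_change_label(self, cfg):
        p = make_record(
            labs=[(0, "HIV ANTIBODY SCREEN", "NONREACTIVE")],
            meds=[(0, "truvada", 28), (0, "dolutegravir", 28)],
        )
        d = classify_hiv_phen(p, cfg)
        assert d.positive  # retained as a (known) false positive
        assert PEP_SUSPECT in d.flags and SAME_DAY_ARV_NEG_SCREEN in d.flags

    def test_icd_codes_are_ignored(self, cfg):
        with_icd = make_record(dx=[(0, "B20", "INPATIENT"), (5, "B20", "OUTPATIENT"),
                                   (9, "Z21", "OUTPATIENT")])
        assert not classify_hiv_phen(with_icd, cfg).positive


class TestPrefilter:
    def test_negative_screening_retained(self, cfg):
        p = make_record(labs=[(0, "HIV ANTIBODY SCREEN", "NONREACTIVE")])
        assert len(prefilter_candidates(Cohort(patients=[p]), cfg)) == 1

    def test_metabolic_panel_only_excluded(self, cfg):
        p = make_record(labs=[(0, "BASIC METABOLIC PANEL", "9")])
        assert len(prefilter_candidates(Cohort(patients=[p]), cfg)) == 0

    def test_prep_medication_retained(self, cfg):
        p = make_record(meds=[(0, "truvada")])
        assert len(prefilter_candidates(Cohort(patients=[p]), cfg)) == 1

    def test_superset_of_every_algorithms_positives(self, cfg):
        rng = np.random.default_rng(11)
        patients = [random_record(rng, f"P{i}") for i in range(60)]
        cohort = Cohort(patients=patients)
        kept = set(prefilter_candidates(cohort, cfg).ids())
        for alg in Algorithm:
            positives = {d.patient_id for d in run_algorithm(cohort, alg, cfg)
                         if d.positive}
            assert positives <= kept


class TestRunAlgorithm:
    def test_one_decision_per_patient_with_evidence(self, cfg):
        patients = [
            make_record("A", labs=[(0, "HIV 1 RNA QUANT PCR", "5000")]),
            make_record("B", meds=[(0, "biktarvy")]),
            make_record("C"),
        ]
        decisions = run_algorithm(Cohort(patients=patients), Algorithm.HIV_PHEN, cfg)
        assert [d.patient_id for d in decisions] == ["A", "B", "C"]
        for d in decisions:
            if d.positive:
                assert d.evidence

    def test_deterministic(self, cfg):
        rng = np.random.default_rng(3)
        cohort = Cohort(patients=[random_record(rng, f"P{i}") for i in range(20)])
        a = run_algorithm(cohort, Algorithm.KRAMER_CRITERIA, cfg)
        b = run_algorithm(cohort, Algorithm.KRAMER_CRITERIA, cfg)
        assert a == b

    def test_unknown_algorithm_fatal(self, cfg):
        with pytest.raises(ValueError, match="unknown algorithm"):
            run_algorithm(Cohort(patients=[]), "MYSTERY", cfg)

    def test_all_five_dispatch(self, cfg):
        cohort = Cohort(patients=[make_record("A", meds=[(0, "biktarvy")])])
        labels = {alg: run_algorithm(cohort, alg, cfg)[0].positive for alg in Algorithm}
        assert labels[Algorithm.HIV_PHEN] and labels[Algorithm.PAUL_LAB]
        assert not labels[Algorithm.FULTZ_ICD_ONLY]


class TestProperties:
    def test_every_criterion_tag_is_evidence_backed(self, cfg):
        rng = np.random.default_rng(21)
        for i in range(100):
            p = random_record(rng, f"P{i}")
            for alg in Algorithm:
                d = run_algorithm(Cohort(patients=[p]), alg, cfg)[0]
                roles = {role for _, role in d.evidence}
                assert d.criteria_met <= roles

    def test_evidence_insertion_never_flips_positive_to_negative(self, cfg):
        rng = np.random.default_rng(42)
        for i in range(200):
            p = random_record(rng, f"P{i}")
            before = {alg: run_algorithm(Cohort(patients=[p]), alg, cfg)[0].positive
                      for alg in Algorithm}
            extra = random_record(rng, p.patient_id)
            grown = dataclasses.replace(
                p,
                diagnoses=p.diagnoses + extra.diagnoses,
                labs=p.labs + extra.labs,
                medications=p.medications + extra.medications,
            )
            after = {alg: run_algorithm(Cohort(patients=[grown]), alg, cfg)[0].positive
                     for alg in Algorithm}
            for alg in Algorithm:
                assert not (before[alg] and not after[alg])

    def test_hiv_phen_labels_unchanged_without_diagnoses(self, cfg):
        rng = np.random.default_rng(7)
        for i in range(100):
            p = random_record(rng, f"P{i}")
            stripped = dataclasses.replace(p, diagnoses=[])
            full = run_algorithm(Cohort(patients=[p]), Algorithm.HIV_PHEN, cfg)[0]
            bare = run_algorithm(Cohort(patients=[stripped]), Algorithm.HIV_PHEN, cfg)[0]
            assert full.label == bare.label

    def test_lower_threshold_never_shrinks_positive_set(self, term):
        rng = np.random.default_rng(13)
        cohort = Cohort(patients=[random_record(rng, f"P{i}") for i in range(80)])
        previous = None
        for t in [1000, 400, 48, 20]:
            cfg = AlgorithmConfig(vl_threshold=t, terminology=term)
            positives = {d.patient_id for d in
                         run_algorithm(cohort, Algorithm.HIV_PHEN, cfg) if d.positive}
            if previous is not None:
                assert previous <= positives
            previous = positives

    def test_confirmatory_and_vl_path_containment_in_hiv_phen(self, cfg):
        # lab/ICD-baseline positives that qualified via confirm+ or high VL
        # must also be HIV-Phen positives
        rng = np.random.default_rng(29)
        for i in range(150):
            p = random_record(rng, f"P{i}")
            cohort = Cohort(patients=[p])
            hiv_phen = run_algorithm(cohort, Algorithm.HIV_PHEN, cfg)[0]
            for alg in (Algorithm.PAUL_LAB, Algorithm.PAUL_ICD):
                d = run_algorithm(cohort, alg, cfg)[0]
                via_lab = d.criteria_met & {"CONFIRMATORY_POS", "VL_GT_THRESHOLD"}
                if d.positive and via_lab:
                    assert hiv_phen.positive


def test_oracle_equivalence_on_random_small_records(cfg):
    """Each classifier agrees with an independently coded brute-force evaluator."""
    rng = np.random.default_rng(2024)
    for i in range(300):
        p = random_record(rng, f"P{i}")
        expected = oracle_labels(p, threshold=cfg.vl_threshold)
        for alg in Algorithm:
            got = run_algorithm(Cohort(patients=[p]), alg, cfg)[0].positive
            assert got == expected[alg.value], (alg, p)
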