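# hivphen

Rule-based identification of people with HIV (PWH) in electronic health
record (EHR) data.

Identifying PWH is the first step of most retrospective HIV research —
care-continuum studies, risk modelling, quality improvement — but manual
chart review does not scale to databases of millions of patients, and
algorithms that rely on ICD diagnosis codes or that mirror the clinical
testing cascade miss patients whose records carry laboratory or medication
evidence of HIV without the corresponding codes or complete test sequences.
`hivphen` implements a criteria-based phenotyping algorithm (HIV-Phen)
designed for that gap, alongside four published baseline algorithms, a
synthetic EHR cohort generator with gold-standard labels, and a
chart-review-style evaluation framework. It is aimed at clinical
informaticists and epidemiologists who need a reproducible, auditable
cohort definition they can re-point at their own local terminology.

## The algorithms

All five classifiers read the same normalized patient record (diagnoses,
labs, medications) through an editable terminology layer. A patient is
classified positive when:

| Algorithm | Rule |
|---|---|
| `HIV_PHEN` | **any 1 of**: positive confirmatory test; viral load (VL) > 1000 copies/mL; antiretroviral (ARV) regimen sufficient to *treat* HIV |
| `FULTZ_ICD_ONLY` | ≥2 outpatient HIV ICD codes on distinct dates, or ≥1 inpatient HIV ICD code |
| `PAUL_LAB` | testing cascade: screen⁺ then confirm⁺; else VL > 1000; else any ARV prescription |
| `PAUL_ICD` | HIV ICD code, confirmed by confirm⁺, VL > 1000, or any ARV prescription |
| `KRAMER_CRITERIA` | any 2 of: HIV ICD code; positive screen/confirm or any VL/CD4 measurement; any ARV prescription |

HIV-Phen ignores diagnosis codes entirely. Its medication criterion
requires a regimen containing at least one anchor agent: a history
consisting only of agents that are also used for hepatitis-B therapy or
pre-exposure prophylaxis (tenofovir products, emtricitabine, lamivudine)
does not qualify on its own, and such patients need a positive confirmatory
test or a VL > 1000 copies/mL instead. Against a review gold standard with
P positives and N negatives, the evaluation reports sensitivity
TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN) and
accuracy (TP+TN)/(P+N), rounded half-up to 2 decimals.

## Worked example

Generate the 360-patient chart-review evaluation preset (a synthetic
cohort whose archetype mix includes complete diagnostic trails, lab-only
and medication-only presentations, ICD code misuse, PEP/PrEP and
hepatitis-B confounders, and notes-only cases invisible to structured
data), then evaluate all five algorithms against its gold labels:

```bash
hivphen simulate --preset chart_review_360 --seed 42 --out demo/cohort
hivphen report --cohort demo/cohort --out demo/report
```

prints

```
hivphen report (360 eligible patients, VL threshold 1000 copies/mL)

      algorithm  sensitivity  specificity  ppv  npv  accuracy  tp  fn  fp  tn
 FULTZ_ICD_ONLY         0.36         0.97 0.91 0.64      0.69  60 106   6 188
       PAUL_LAB         0.84         0.89 0.87 0.87      0.87 140  26  21 173
       PAUL_ICD         0.36         1.00 1.00 0.65      0.71  60 106   0 194
KRAMER_CRITERIA         0.36         0.97 0.92 0.64      0.69  60 106   5 189
       HIV_PHEN         0.98         0.95 0.95 0.98      0.96 162   4   9 185

HIV-Phen positives: 171 (tp=162 fn=4 fp=9 tn=185)
criterion breakdown:
  CONFIRMATORY_POS: 82 (47.95% of positives)
    without HIV ICD code or positive screen: 22 (26.83%)
  VL_GT_THRESHOLD: 100 (58.48% of positives)
    without HIV ICD code or positive screen: 40 (40.00%)
  ARV_TREATMENT: 109 (63.74% of positives)
    without HIV ICD code or positive screen: 49 (44.95%)
```

The HIV-Phen row — 162 true positives, 4 false negatives (notes-only
patients), 9 false positives (post-exposure prophylaxis courses), 185 true
negatives, hence sensitivity 0.98 and accuracy 0.96 — is fixed by the
preset's archetype composition and holds for every seed; the baseline rows
show how much of this synthetic cohort each code- or cascade-based rule
can see. The criterion breakdown counts overlap (one patient can meet
several criteria) and reports, per criterion, how many qualifying patients
have neither an HIV ICD code nor a positive screening test — the patients
a code- or cascade-anchored algorithm cannot find.

Other commands: `hivphen phenotype` (decisions for one or all algorithms),
`hivphen evaluate` (one decisions file vs gold), `hivphen compare`,
`hivphen threshold-scan` (HIV-Phen positives at VL cut-offs such as
1000/400/48/20 copies/mL), and `hivphen simulate --spec my_cohort.yaml`
for custom archetype mixtures. The same operations are available as
library functions (`hivphen.generate_cohort`, `hivphen.run_algorithm`,
`hivphen.compare_algorithms`, ...).

Deployments should replace the shipped terminology defaults
(`src/hivphen/config/*.tsv`) with locally curated code, lab-test and
medication lists — lab test names in particular are not standardized
across institutions.

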