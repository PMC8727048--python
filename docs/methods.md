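# Methods

## The phenotyping problem and the model

The package classifies patients in longitudinal EHR extracts as people
with HIV (PWH) or not, from three structured evidence streams: diagnosis
codes (ICD-9/ICD-10), laboratory results, and medication orders. All five
implemented classifiers are deterministic rules over per-patient evidence
predicates; nothing is estimated from data. The predicates are:

- **HIV ICD code** — membership of a normalized code (uppercase, dot-free)
  in a named code set, with exact and prefix entries per coding system.
- **Positive screening test** — an antibody/antigen screening assay whose
  qualitative result maps to POSITIVE through a configurable synonym table
  (REACTIVE, DETECTED, ...).
- **Positive confirmatory test** — Western blot, immunofluorescence assay,
  or an HIV-1/2 differentiation assay (MultiSpot/Geenius) with a positive
  result.
- **Viral load above threshold** — a quantitative HIV RNA result strictly
  greater than the configured cut-off (default 1000 copies/mL).
- **ARV exposure / regimen sufficiency** — any antiretroviral ingredient
  ever prescribed; separately, whether the patient's complete ARV
  ingredient history contains at least one anchor ("core") agent.
  Ingredient histories that are a subset of the hepatitis-B/PrEP-capable
  agents (tenofovir products, emtricitabine, lamivudine) are classed
  AMBIGUOUS_ONLY and never satisfy HIV-Phen's medication criterion alone.

HIV-Phen is the disjunction of the last three (confirm⁺ ∨ VL > t ∨
treatment-sufficient regimen) and deliberately ignores ICD codes: its
design premise is that laboratory and prescription evidence identifies PWH
whose encounters were never coded for HIV. The four baselines (ICD-only,
lab cascade, ICD-with-confirmation, 2-of-3 criteria) are reproduced as
published, including the lab cascade's medication arm accepting *any* ARV
prescription with no regimen-sufficiency screen — only HIV-Phen applies
the ambiguity rule.

### Assumptions

- Criteria are presence-of-result rules at date precision; no temporal
  ordering between screening and confirmatory results is enforced. The
  outpatient-code criterion of the ICD-only rule requires distinct
  calendar dates so duplicated same-day billing rows cannot qualify.
- Regimen ambiguity is evaluated over the entire record, not per-date
  windows: a patient who ever received an anchor agent is
  treatment-sufficient.
- Eligibility (age ≥13 years, the age at which routine HIV screening is
  recommended) is assessed at the patient's latest recorded event, the
  only reference date that is always defined in a multi-year extract;
  patients with no events are excluded with a logged count.

## Tunable parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `vl_threshold` | 1000 | copies/mL | spans the historical change in assay detection limits (400 → 48 → 20) and guards against misreading acute-infection workups with negative differentiation assays |
| `min_age_years` | 13 | years | screening-guideline age floor |
| `prefilter` | on | — | candidate funnel (any HIV code, any HIV-related lab regardless of result, any ARV); a strict superset of every algorithm's positives, used only to shrink the working set |
| `kramer_icd9_only` | off | — | the original 2-of-3 rule predates ICD-10; the default accepts both systems because modern extracts span the transition |
| Cochran sampling | 95% / 5% | confidence / margin | standard review-subsample computation with p=0.5, no finite-population correction (n=385 at the defaults); the subsample size is also directly settable |

## Numerical and parsing choices

- **Censored viral loads.** "<N" and textual undetectable results carry
  `detectable = False`. They never satisfy a ">t" comparison — provably
  correct for t ≥ N, and adopted as the conservative choice for t < N as
  well, since a censored result demonstrates no detectable viraemia.
  ">N" results satisfy any threshold strictly below N. Unparseable values
  are retained but flagged unusable and contribute to no criterion, with a
  logged count (loading never silently drops evidence).
- **Lab-name mapping** is ordered case-insensitive substring matching,
  first match wins, with confirmatory and RNA patterns ahead of the
  generic screening fallbacks; unmapped names are OTHER and inert. The
  shipped tables are explicit stand-ins: test names are not standardized
  across institutions and every deployment should curate its own
  (`src/hivphen/config/`, read and re-serialized byte-identically).
- **Rounding** of reported metrics and percentages is decimal half-up at
  2 places, matching how printed evaluation tables round; raw ratios are
  kept alongside. Zero-denominator metrics are reported absent, never 0.
- **Advisory flags never change labels.** `PEP_SUSPECT` (one short fully
  covered regimen episode of ≤35 days) and `SAME_DAY_ARV_NEG_SCREEN`
  (ARV start on the day of a negative screen) mark the known
  false-positive patterns; filtering on them would also drop PWH who are
  out of care or non-adherent, so they are surfaced for review instead.
  `NO_ICD_NO_POS_SCREEN` marks positives invisible to code/screen-anchored
  algorithms.

## The synthetic cohort generator

Real HIV cohorts cannot be redistributed, so evaluation runs on generated
cohorts with known gold labels. Eleven archetypes emulate the diagnostic
trajectories and confounders the classifiers must separate: FULL_TRAIL
(screen⁺ → confirm⁺ → VL > 1000 → ART, ICD-coded), VL_ONLY, ARV_ONLY,
CONFIRM_ONLY, ICD_ONLY_MISUSE (codes without disease), WORKUP_ONLY (code
plus CD4/VL orders with negative/low results), PEP, PREP, HBV_MONO,
NOTES_ONLY_HIV (gold-positive with a benign structured record), and
BACKGROUND. Each archetype fixes its gold label and a structural promise,
so the expected decision of every algorithm on every archetype is a
hand-derived 11×5 truth table shipped as `EXPECTED_LABELS` and enforced by
tests across seeds.

Event-level details are plain defaults, chosen once: untreated
gold-positive viral loads are log-uniform on 10^3.1–10^6 copies/mL (only
the threshold crossing matters to the rules), CD4 counts uniform in
plausible clinical ranges, regimens are standard combination products,
PEP courses are ~28-day single episodes bracketed by negative screens, and
WORKUP_ONLY viral loads are undetectable or detectable below 1000
copies/mL (so lowering the threshold recruits a small number of additional
positives, as a threshold scan should reveal). Demographic fields are
drawn from configurable categorical marginals; surveillance-style presets
(~24% female; Black > White pluralities) and a generic outpatient-EHR
preset are provided. Generation uses one root seed with a substream per
patient index: identical spec and seed give byte-identical tables, and
editing the mixture does not perturb unrelated patients.

The `chart_review_360` preset fixes exact archetype counts
(60 FULL_TRAIL + 40 VL_ONLY + 40 ARV_ONLY + 22 CONFIRM_ONLY = 162
detectable positives; 4 NOTES_ONLY_HIV; 9 PEP; 185 structurally negative
records) so that HIV-Phen's confusion row against gold is
(162, 4, 9, 185) by construction, for every seed. This makes the
end-to-end evaluation pipeline — simulate, phenotype, evaluate —
deterministic at the level that matters while the records themselves vary
with the seed.

### What the generator does and does not show

The generator reproduces the *logical* structure of EHR evidence, not its
epidemiology: archetype frequencies are design choices, comorbidity
co-occurrence, visit cadence and laboratory noise are schematic, and
clinical-note text does not exist (NOTES_ONLY_HIV patients simply have
benign structured records). Passing tests therefore demonstrate that the
classifiers implement their rules exactly, that the evaluation machinery
reproduces published-table arithmetic, and that the rule set behaves
correctly on the documented confounders — not that any particular
sensitivity or specificity will be attained on a real institution's data,
which depends on local coding practice and terminology curation.

## Problem sizes

The shipped test and acceptance runs use deliberately small problems: the
360-patient evaluation preset, truth-table checks at 2–4 patients per
archetype across ≥20 seeds, 1000-record randomized oracle-equivalence
checks against an independently coded brute-force rule evaluator, 10,000
random evidence-insertion perturbations for monotonicity, and a
10,000-patient cohort for demographic-marginal checks. The rules are
per-patient and embarrassingly parallel; cohort size only scales run time
linearly.

## Known limitations

- No ontology resolution (LOINC/RxNorm): terminology is keyword- and
  list-based by design, and must be curated per deployment.
- The inpatient/outpatient flag is taken as given on each diagnosis row;
  how a source system derives it is out of scope.
- The ICD-with-confirmation baseline's entry point uses the same HIV code
  set as the ICD-only rule; an extended comorbidity entry list can be
  supplied via the terminology config but no default is shipped.
- The medication path of HIV-Phen is not logically contained in the lab
  cascade's (nor vice versa); the containment guarantee tested is for the
  confirmatory and viral-load paths only.
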