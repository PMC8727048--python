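# Default terminology for the HIV phenotyping algorithms.
#
# These tables are clinically standard DEFAULTS and are intended to be
# replaced with locally curated lists: laboratory test names are not
# standardized across institutions, so every deployment should review
# and extend lab_tests.tsv (and the code/medication tables) against its
# own data before trusting cohort output.
version: hivphen-default-1
tables:
  icd_codes: icd_codes.tsv
  lab_tests: lab_tests.tsv
  medications: medications.tsv
qualitative_synonyms:
  POSITIVE:
    - POSITIVE
    - POS
    - REACTIVE
    - REPEATEDLY REACTIVE
    - DETECTED
    - PRELIMINARY POSITIVE
  NEGATIVE:
    - NEGATIVE
    - NEG
    - NONREACTIVE
    - NON-REACTIVE
    - NOT REACTIVE
    - NOT DETECTED
  INDETERMINATE:
    - INDETERMINATE
    - EQUIVOCAL
    - INCONCLUSIVE
    - BORDERLINE
undetectable_synonyms:
  - NOT DETECTED
  - UNDETECTABLE
  - UNDETECTED
  - TARGET NOT DETECTED
  - TND
  - ND
  - BELOW LIMIT OF DETECTION
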