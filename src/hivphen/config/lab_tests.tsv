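pattern	category
GEENIUS	CONFIRMATORY
MULTISPOT	CONFIRMATORY
DIFFERENTIATION	CONFIRMATORY
WESTERN BLOT	CONFIRMATORY
HIV IFA	CONFIRMATORY
IMMUNOFLUORESCENCE	CONFIRMATORY
HIV 1 RNA	VIRAL_LOAD
HIV-1 RNA	VIRAL_LOAD
HIV1 RNA	VIRAL_LOAD
HIV RNA	VIRAL_LOAD
HIV VIRAL LOAD	VIRAL_LOAD
HIV QUANT	VIRAL_LOAD
HIV PCR	VIRAL_LOAD
CD4	CD4
T HELPER	CD4
T-HELPER	CD4
HIV AG/AB	SCREENING
HIV 1/2 AG/AB	SCREENING
HIV COMBO	SCREENING
HIV 4TH GEN	SCREENING
HIV ANTIGEN	SCREENING
HIV ANTIBODY	SCREENING
HIV AB	SCREENING
HIV SCREEN	SCREENING
HIV RAPID	SCREENING
RAPID HIV	SCREENING
HIV ELISA	SCREENING
HIV EIA	SCREENING
HUMAN IMMUNODEFICIENCY VIRUS	SCREENING
HIV	SCREENING
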