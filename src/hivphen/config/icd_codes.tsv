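set_name	system	code	match_mode
hiv	ICD9	042	PREFIX
hiv	ICD9	V08	EXACT
hiv	ICD9	07953	EXACT
hiv	ICD9	79571	EXACT
hiv	ICD10	B20	EXACT
hiv	ICD10	B9735	EXACT
hiv	ICD10	Z21	EXACT
hiv	ICD10	O987	PREFIX
hiv	ICD10	R75	EXACT
hbv	ICD9	07030	EXACT
hbv	ICD9	07032	EXACT
hbv	ICD10	B180	EXACT
hbv	ICD10	B181	EXACT
hbv	ICD10	B1910	EXACT
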