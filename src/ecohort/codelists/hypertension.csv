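system,pattern,match_mode,condition,category
ICD10,I10,prefix,hypertension,
ICD10,I11,prefix,hypertension,
ICD9,401,prefix,hypertension,
READ2,G2,prefix,hypertension,
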