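system,pattern,match_mode,condition,category
ICD10,E10,prefix,diabetes,
ICD10,E11,prefix,diabetes,
ICD9,250,prefix,diabetes,
READ2,C10,prefix,diabetes,
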