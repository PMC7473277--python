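system,pattern,match_mode,condition,category
ICD10,I63,prefix,stroke,
ICD10,I64,exact,stroke,
ICD9,434,prefix,stroke,
READ2,G66,prefix,stroke,
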