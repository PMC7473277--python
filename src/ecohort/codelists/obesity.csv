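system,pattern,match_mode,condition,category
ICD10,E66,prefix,obesity,
ICD9,278,prefix,obesity,
READ2,C380,prefix,obesity,
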