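system,pattern,match_mode,condition,category
ICD10,F17,prefix,ever_smoking,
ICD9,3051,exact,ever_smoking,
READ2,137R,exact,ever_smoking,
READ2,137S,exact,ever_smoking,
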