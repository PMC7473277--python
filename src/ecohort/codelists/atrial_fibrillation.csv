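system,pattern,match_mode,condition,category
ICD10,I48,prefix,atrial_fibrillation,
ICD9,42731,exact,atrial_fibrillation,
READ2,G573,prefix,atrial_fibrillation,
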