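system,pattern,match_mode,condition,category
ICD10,F00,prefix,dementia,AD
ICD10,G30,prefix,dementia,AD
ICD10,F01,prefix,dementia,VaD
ICD10,F02,prefix,dementia,
ICD10,F03,prefix,dementia,
ICD10,G318,exact,dementia,DLB
ICD10,G310,exact,dementia,FTD
ICD9,290,prefix,dementia,
ICD9,2904,prefix,dementia,VaD
ICD9,3310,exact,dementia,AD
ICD9,3311,exact,dementia,FTD
ICD9,33182,exact,dementia,DLB
READ2,Eu00,prefix,dementia,AD
READ2,F110,prefix,dementia,AD
READ2,Eu01,prefix,dementia,VaD
READ2,Eu02,prefix,dementia,
READ2,E00,prefix,dementia,
READ2,Eu025,exact,dementia,DLB
READ2,F112,exact,dementia,FTD
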