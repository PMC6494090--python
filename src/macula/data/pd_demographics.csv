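subject_id,age_years,sex,updrs_motor,age_at_diagnosis,diagnosis_age_confirmed,on_levodopa,age_dopa_started,other_medications
JC_0702,44,F,,40,yes,yes,43,
JC_0703,66,F,33,65,no,yes,65,Amantadine
JC_0705,65,F,10,60,yes,no,,Amantadine
JC_0706,57,M,,57,yes,yes,57,Ropinirole
JC_0708,53,M,13,51,yes,yes,51,
JC_0709,51,M,16,43,yes,yes,46,
JC_0710,56,F,37,53,yes,no,,Ropinirole
JC_0712,54,M,8,53,no,no,,Amantadine; Pramipexole
JC_0715,87,F,35,84,no,yes,84,
JC_0719,77,M,24,75,yes,yes,76,
JC_0721,71,F,4,67,no,yes,67,
JC_0724,49,M,25,40,yes,yes,40,Ropinirole
JC_0725,78,M,,73,yes,yes,75,
JC_0727,61,M,7,57,yes,yes,61,Ropinirole
JC_0728,68,M,16,57,yes,yes,62,
JC_0729,70,F,21,64,yes,yes,64,
JC_0731,76,F,11,74,yes,yes,74,
JC_0733,79,F,,67,no,yes,67,Amantadine; Ropinirole
JC_0737,59,M,23,56,yes,yes,56,Entacapone; Ropinirole
JC_0738,71,M,16,69,yes,yes,69,
JC_0739,64,M,9,62,yes,yes,62,Amantadine; Selegiline
JC_0743,61,F,14,60,yes,yes,60,
JC_0745,64,M,,58,yes,yes,60,Trihexyphendiyl; Ropinirole
JC_0748,76,M,9,75,yes,yes,75,
JC_0750,56,M,13,53,yes,no,,Pramipexole
JC_0950,53,M,6,46,yes,yes,46,Amantadine; Rasagiline
JC_0951,70,F,19,69,yes,yes,69,
JC_0953,53,F,5,48,yes,no,,Amantadine; Rasagiline; Ropinirole
JC_0955,76,M,31,72,yes,yes,74,
JC_0957,58,M,14,57,yes,no,,Amantadine; Pramipexole
JC_0958,70,M,19,66,yes,yes,66,Amantadine
JC_0959,70,M,23,58,yes,yes,60,Amantadine; Ropinirole
JC_0960,69,F,16,68,yes,no,,Amantadine
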