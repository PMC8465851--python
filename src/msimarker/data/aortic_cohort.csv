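patient_id,subgroup,gender,age,diameter_mm,comorbidities
TAA_1,TAA,M,62,58,CAD;HI
TAA_2,TAA,M,67,59,HI
TAA_3,TAA,M,54,52,HI
TAA_4,TAA,M,43,57,HI
TAA_5,TAA,M,68,46,CAD;HI;AHT;HLP;COPD;CRF
AAA_1,AAA,M,78,60,CAD;AHT;HLP
AAA_2,AAA,M,72,81,CRF;AHT
AAA_3,AAA,M,78,80,CAD;HLP
AAA_4,AAA,M,63,110,AHT
AAA_5,AAA,M,76,68,CAD;HI;AHT
EVAR_1,EVAR,M,67,75,CAD;PAD;AHT
EVAR_2,EVAR,M,64,90,CAD;AHT;HLP
EVAR_3,EVAR,M,80,65,AF;PAD
EVAR_4,EVAR,M,73,59,CAD;CRF
EVAR_5,EVAR,M,65,69,AHT;PAD
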