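cohort,age_bin,n_male,n_female
Korean,21-30,116,61
Korean,31-40,24,13
Korean,41-50,26,13
Korean,51-60,23,8
Korean,61-70,21,31
Korean,71-80,8,17
Korean,81-90,0,0
IXI,21-30,45,55
IXI,31-40,60,39
IXI,41-50,41,48
IXI,51-60,38,61
IXI,61-70,47,71
IXI,71-80,15,34
IXI,81-90,5,3
ADNI,21-30,0,0
ADNI,31-40,0,0
ADNI,41-50,0,0
ADNI,51-60,12,35
ADNI,61-70,134,200
ADNI,71-80,195,215
ADNI,81-90,67,51
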