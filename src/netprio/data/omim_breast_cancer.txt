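NQO1
XRCC3
BRCD2
PALB2
ESR1
RAD51A
PPM1D
PIK3CA
ATM
SLC22A1L
TP53
KRAS2
TSG101
PHB
HMMR
RB1CC1
BRCA2
BRCA3
BRIP1
CASP8
RAD54L
CDH1
CHEK2
BRCD1
AKT1
BRCATA
BCPR
BARD1
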