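IL1RN
IL1B
IRF1
KLF6
APC
PIK3CA
CASP10
CDH1
ERBB2
MUTYH
FGFR2
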