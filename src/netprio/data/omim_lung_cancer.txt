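TSG11
CHRNA3
CHRNA5
DDX26
MPO
BRAF
DLEC1
LNCR1
EGFR
RASSF1
IRF1
LNCR4
CASP8
LNCR3
CYP2A6
PIK3CA
PPP2R1B
SLC22A1L
ERCC6
MAP3K8
KRAS2
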