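CRCS6
CRCS7
DCC
MLH1
CRCS5
CRCS2
PLA2G2A
AXIN2
BRAF
MSH2
SMAD7
MLH3
MCC
TGFBR2
CRCS8
PDGFRL
CRCS9
TLR2
HMPS1
APC
PIK3CA
DLC1
BUB1B
MSH6
BAX
TLR4
FGFR3
TP53
CTNNB1
CRCS11
CRCS10
FLCN
NRAS
CCND1
EP300
CHEK2
AKT1
BUB1
PMS2
PMS1
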