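MSR1
ZFHX3
ELAC2
HPCQTL19
AR
EHBP1
KLF6
HPC3
HPC5
HPC4
HPC7
HPC6
HPC9
MAD1L1
HIP1
HPC11
HPC10
RNASEL
PCAP
CD82
HPC15
HPC14
HPCX2
PTEN
BRCA2
HPCX1
MXI1
CHEK2
EPHB2
MSMB
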