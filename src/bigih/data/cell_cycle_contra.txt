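CCND1
BAX
ACIN1
MTDH
ATRX
CD44
CCND2
BTG2
PA2G4
Brd4
CSNK2A1
FOXO1
CDK11A
PMEPA1
CAMK2N1
EGFR
HSPB1
CDK19
PRKAA2
CDH13
GSK3B
KRAS
CDT1
PTPRF
ENTPD5
SMARCA4
MAPK8
CEBPD
RSF1
THOC2
SOX2
NFIX
CYP1B1
SETD8
TPR
SP1
PTK2B
DEK
SRPK2
STAT3
SPP1
GADD45G
TBL1XR1
TOP2A
KLF6
TIMP1
MAFB
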