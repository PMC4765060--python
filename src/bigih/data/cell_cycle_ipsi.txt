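ATF3
BAG3
BCL2A1
NEK6
ATRX
CASP3
CASP7
BTG2
NFIX
Brd4
CCND1
CCNA2
CAMK2N1
PA2G4
CYP1B1
CD44
CDKN1B
Ccl2
PDLIM7
CDK1
CEBPD
CDK11A
PMEPA1
CEBPB
CREM
CDT1
PRDM2
CREB1
FOSL1
DEK
PTPRF
CREBBP
HSPA1A/HSPA1B
ETV5
RAB35
CSNK2A1
HSPB1
FGF2
SETD8
EGFR
IKBKB
FLNA
SRPK2
ELAVL1
IL1B
GADD45G
SUDS3
FN1
KLF4
HMOX1
TBL1XR1
GSK3B
KPNB1
HSPA2
TCEB3
MDM2
MCL1
IL6R
THOC2
NFE2L2
MCM2
KLF6
TIMP1
SMARCA4
MITF
LATS1
TNFRSF1A
STAT3
PTGS2
MCM8
TOP2A
SPP1
MMS22L
TPR
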