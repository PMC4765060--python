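network_id	gene
1	CALB1
1	CDCA7L
1	CMIP
1	DAB2
1	FLNA
1	GCLM
1	GFAP
1	NFE2L2
1	PDLIM7
2	ANXA1
2	ATF3
2	BAG3
2	CCNA2
2	CDK1
2	CDKN1B
2	ETV5
2	FN1
2	LATS1
2	MCL1
2	MCM2
2	MCM8
2	MMS22L
2	NAA15
2	RAB35
2	SPIN1
2	TAGLN2
2	THOC2
2	TJP2
2	UNC5B
3	BCL11A
3	CCND1
3	CREB1
3	CREBBP
3	CSRNP1
3	DES
3	IKBKB
3	ITPR2
3	KLF6
3	KPNB1
3	MITF
3	NFIX
3	PTGR1
3	RAI14
3	RRM2
3	SENP2
3	SMARCA4
3	SUDS3
3	TBL1XR1
3	TGM2
3	THRA
4	ALB
4	BTG2
4	Ccl2
4	CCL3L3
4	CCL4
4	Ccl6
4	Ccl7
4	CD36
4	CEBPB
4	CREM
4	CX3CL1
4	CXCL3
4	Cxcl9
4	DUSP5
4	EGR2
4	FGF2
4	FGL2
4	FOSL1
4	HMOX1
4	IL1B
4	IL6R
4	ITGB2
4	KLF4
4	NEK6
4	PDE4B
4	PTGS2
4	SPP1
4	TLR4
5	ACSL5
5	CAMK2N1
5	CHSY1
5	ELAVL1
5	MAP4K4
5	MSI2
5	PTGER3
5	TCEB3
5	TMEM123
5	TRAF6
5	WFS1
6	ARL11
6	CAMK1G
6	CASP3
6	CISD2
6	CLN5
6	DNAJB6
6	DNAJB9
6	FGR
6	HCK
6	HSPA1A/HSPA1B
6	HSPA2
6	HSPA9
6	HSPB8
6	MDM2
6	PCDH15
6	PI4K2A
6	PRDM2
6	SGPL1
6	SNCA
6	SRPK2
6	TMEM109
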