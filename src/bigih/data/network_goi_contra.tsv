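network_id	gene
1	ACIN1
1	ACVR1C
1	CD44
1	DPYD
1	FGL2
1	MAPK8
1	MTDH
1	RAD23B
1	TTLL1
2	AURKAIP1
2	BTG2
2	CCND1
2	LCN2
2	MAFG
2	PIK3CD
2	PIK3R2
2	RND3
2	SETD8
2	SOX2
2	TRPM7
2	ZMYND11
2	ZNF148
3	AHI1
3	CDK11A
3	CDK19
3	DNAJB6
3	HSP90AA1
3	HSPB1
3	KLF13
3	LINGO1
3	MED1
3	PA2G4
3	PPP3CB
3	THRA
3	TUFM
4	EIF5B
4	ENTPD5
4	FOXO1
4	KRAS
4	MEF2A
4	PALLD
4	PRKAA2
4	PTK2B
4	RASSF4
4	Serbp
5	ATP2A2
5	ATP2B2
5	BAX
5	CDH13
5	GBX2
5	GSK3B
5	KCND2
5	MAFB
5	MFN1
5	NDUFAB1
5	PRKAA2
6	CCDC86
6	CCND2
6	CEBPD
6	GSK3B
6	PRLR
6	PSIP1
6	RSF1
6	SP1
6	SPP1
6	TIMP1
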