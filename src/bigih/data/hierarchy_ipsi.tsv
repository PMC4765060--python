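gene	fold_change	tier	compartment
ATF3	12.027	primary	Nucleus
CCND1	2.152	primary	Nucleus
CEBPB	3.366	primary	Nucleus
CREB1	2.666	primary	Nucleus
CREBBP	2.421	primary	Nucleus
MDM2	2.01	primary	Nucleus
NFE2L2	2.452	primary	Nucleus
SMARCA4	2.521	primary	Nucleus
STAT3	4.219	primary	Nucleus
CDK1	2.105	primary	Nucleus
CSNK2A1	2.992	primary	Cytoplasm
EGFR	6.773	primary	Plasma Membrane
GSK3B	-2.733	primary	Nucleus
CD44	15.558	primary	Plasma Membrane
FN1	3.97	primary	Extracellular Space
TRAF6	2.163	primary	Cytoplasm
CASP3	2.535	primary	Cytoplasm
ELAVL1	3.275	primary	Cytoplasm
CEBPD	11.271	secondary	Nucleus
CREM	2.165	secondary	Nucleus
EGR2	2.271	secondary	Nucleus
FOSL1	5.875	secondary	Nucleus
KLF4	2.057	secondary	Nucleus
MITF	4.755	secondary	Nucleus
TCF4	-2.216	secondary	Nucleus
HSPA1A/HSPA1B	3.137	secondary	Cytoplasm
MCM2	2.57	secondary	Nucleus
PTGS2	3.106	secondary	Cytoplasm
IL1B	5.166	secondary	Extracellular Space
SPP1	37.905	secondary	Extracellular Space
CDKN1B	3.732	secondary	Nucleus
IKBKB	2.127	secondary	Cytoplasm
KPNB1	3.173	secondary	Nucleus
MCL1	3.25	secondary	Cytoplasm
THRA	-2.799	secondary	Nucleus
CASP7	2.579	secondary	Cytoplasm
BAG3	4.045	secondary	Cytoplasm
CCNA2	2.633	secondary	Nucleus
GFAP	3.011	secondary	Cytoplasm
HSPA9	2.666	secondary	Cytoplasm
HSPB1	46.922	secondary	Cytoplasm
SNCA	-2.169	secondary	Cytoplasm
ACSL5	-2.361	peripheral	Cytoplasm
ANXA1	3.535	peripheral	Plasma Membrane
CHSY1	2.873	peripheral	Cytoplasm
CP	27.838	peripheral	Extracellular Space
EHD4	2.361	peripheral	Plasma Membrane
GCLM	2.019	peripheral	Cytoplasm
HMOX1	9.778	peripheral	Cytoplasm
MCM8	2.027	peripheral	Nucleus
MX1	28.177	peripheral	Cytoplasm
PDE4B	5.602	peripheral	Cytoplasm
RAB35	2.086	peripheral	Cytoplasm
RRM2	3.34	peripheral	Nucleus
SDC1	13.681	peripheral	Plasma Membrane
SETD8	2.029	peripheral	Nucleus
SGPL1	3.108	peripheral	Cytoplasm
SRXN1	6.306	peripheral	Cytoplasm
TGM2	3.574	peripheral	Cytoplasm
TOP2A	2.26	peripheral	Nucleus
BCL11A	-2.38	peripheral	Nucleus
BTG2	-2.22	peripheral	Nucleus
CCAR1	-2.943	peripheral	Nucleus
CSRNP1	2.821	peripheral	Nucleus
DEK	-3.006	peripheral	Nucleus
DNAJB6	-4.383	peripheral	Nucleus
ETV5	-2.163	peripheral	Nucleus
KLF13	-2.006	peripheral	Nucleus
KLF6	6.003	peripheral	Nucleus
NAA15	3.605	peripheral	Nucleus
NFIX	-2.548	peripheral	Nucleus
NFKB2	2.768	peripheral	Nucleus
PA2G4	-2.702	peripheral	Nucleus
PRDM2	3.677	peripheral	Nucleus
TBL1XR1	2.587	peripheral	Nucleus
TCEB3	3.053	peripheral	Nucleus
CAMK1G	-2.271	peripheral	Cytoplasm
CAMK2N1	-11.813	peripheral	Plasma Membrane
CARD11	7.343	peripheral	Cytoplasm
CDK11A	-4.29	peripheral	Nucleus
FGR	3.915	peripheral	Nucleus
HCK	3.887	peripheral	Cytoplasm
HSPB8	4.112	peripheral	Cytoplasm
LATS1	2.003	peripheral	Nucleus
MAP4K4	2.258	peripheral	Cytoplasm
NEK6	2.322	peripheral	Nucleus
SRPK2	-5.614	peripheral	Nucleus
TJP2	2.552	peripheral	Plasma Membrane
Ccl2	195.455	peripheral	Extracellular Space
CCL3L3	5.269	peripheral	Extracellular Space
CCL4	2.162	peripheral	Extracellular Space
Ccl6	10.291	peripheral	Extracellular Space
Ccl7	124.78	peripheral	Extracellular Space
CXCL3	13.211	peripheral	Extracellular Space
Cxcl9	2.846	peripheral	Extracellular Space
TIMP1	38.486	peripheral	Extracellular Space
IL6R	2.315	peripheral	Plasma Membrane
IL6ST	2.307	peripheral	Plasma Membrane
ITGB2	2.675	peripheral	Plasma Membrane
TLR4	2.699	peripheral	Plasma Membrane
TNFRSF1A	3.555	peripheral	Plasma Membrane
UNC5B	2.067	peripheral	Plasma Membrane
ALB	-3.125	peripheral	Extracellular Space
LCN2	71.824	peripheral	Extracellular Space
RASA1	2.392	peripheral	Cytoplasm
TPR	2.212	peripheral	Nucleus
FGL2	16.793	peripheral	Extracellular Space
SENP2	2.051	peripheral	Nucleus
DUSP5	3.285	peripheral	Nucleus
PTPRF	-6.365	peripheral	Plasma Membrane
EIF3C	-4.369	peripheral	Other
EIF5B	-3.044	peripheral	Cytoplasm
FGF2	2.387	peripheral	Extracellular Space
KCND2	-2.792	peripheral	Plasma Membrane
AHI1	2.243	peripheral	Cytoplasm
BCL2A1	3.055	peripheral	Cytoplasm
CALB1	-2.091	peripheral	Cytoplasm
CD68	4.365	peripheral	Plasma Membrane
CDCA7L	2.648	peripheral	Nucleus
CDT1	3.098	peripheral	Nucleus
CISD2	-7.833	peripheral	Cytoplasm
CMIP	-3.778	peripheral	Cytoplasm
DAB2	3.053	peripheral	Plasma Membrane
DES	2.857	peripheral	Cytoplasm
DNAJB9	2.128	peripheral	Nucleus
FLNA	3.45	peripheral	Cytoplasm
GADD45G	3.191	peripheral	Nucleus
HLA-A	9.296	peripheral	Plasma Membrane
HSPA2	3.51	peripheral	Cytoplasm
LCP1	6.082	peripheral	Cytoplasm
LSP1	11.716	peripheral	Cytoplasm
MMS22L	2.918	peripheral	Nucleus
MSI2	2.288	peripheral	Cytoplasm
PDLIM7	4.695	peripheral	Cytoplasm
PHLDA1	5.129	peripheral	Cytoplasm
PMEPA1	2.682	peripheral	Plasma Membrane
PSIP1	-2.663	peripheral	Nucleus
RDX	4.828	peripheral	Cytoplasm
SERPINA3	58.488	peripheral	Extracellular Space
SPIN1	2.178	peripheral	Nucleus
SUDS3	2.228	peripheral	Nucleus
TAGLN2	3.891	peripheral	Cytoplasm
THOC2	2.119	peripheral	Nucleus
TMEM109	2.106	peripheral	Cytoplasm
TMEM123	2.348	peripheral	Plasma Membrane
CYP1B1	10.998	orphan	Cytoplasm
KIF3A	-5.083	orphan	Cytoplasm
PTGR1	2.258	orphan	Cytoplasm
RND3	2.864	orphan	Cytoplasm
WFS1	2.083	orphan	Cytoplasm
ITPR2	2.489	orphan	Cytoplasm
KCNN4	3.088	orphan	Plasma Membrane
ATRX	2.091	orphan	Nucleus
RAI14	3.284	orphan	Nucleus
CX3CL1	-2.044	orphan	Extracellular Space
PTGER3	2.425	orphan	Plasma Membrane
PI4K2A	2.96	orphan	Cytoplasm
CD36	5.08	orphan	Plasma Membrane
ARL11	3.143	orphan	Other
Brd4	-3.528	orphan	Nucleus
CLN5	2.041	orphan	Cytoplasm
Ctdspl	-7.271	orphan	Cytoplasm
KIFAP3	-2.281	orphan	Cytoplasm
Nos1ap	-2.698	orphan	Other
PCDH15	2.147	orphan	Plasma Membrane
RASSF4	4.289	orphan	Other
Rbm25	-5.547	orphan	Nucleus
Slpi	82.908	orphan	Cytoplasm
Tpm3	2.592	orphan	Cytoplasm
TRIM54	-4.426	orphan	Cytoplasm
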