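gene	fold_change	tier	compartment
CCND1	-2.027	primary	Nucleus
MED1	-4.011	primary	Nucleus
SMARCA4	-7.712	primary	Nucleus
SOX2	-4.791	primary	Nucleus
SP1	-2.076	primary	Nucleus
STAT3	-3.771	primary	Nucleus
CSNK2A1	-2.75	primary	Cytoplasm
EGFR	2.374	primary	Plasma Membrane
GSK3B	-6.635	primary	Nucleus
CD44	2.399	primary	Plasma Membrane
HSP90AA1	-4.843	primary	Cytoplasm
FOXO1	-3.329	secondary	Nucleus
MEF2A	-6.31	secondary	Nucleus
NFIX	-8.112	secondary	Nucleus
TCF4	-4.625	secondary	Nucleus
MAPK8	2.102	secondary	Cytoplasm
PIK3R2	2.332	secondary	Cytoplasm
PTK2B	2.15	secondary	Cytoplasm
KRAS	-2.027	secondary	Cytoplasm
TOP2A	-2.406	secondary	Nucleus
ATP2A2	-2.607	secondary	Cytoplasm
BAX	-3.306	secondary	Cytoplasm
SPP1	2.37	secondary	Extracellular Space
THRA	-11.518	secondary	Nucleus
TUFM	-2.109	secondary	Cytoplasm
CCND2	-3.617	secondary	Nucleus
HSPB1	2.639	secondary	Cytoplasm
BTG2	-5.803	peripheral	Nucleus
CCAR1	-11.648	peripheral	Nucleus
CEBPD	2.037	peripheral	Nucleus
DEK	-7.352	peripheral	Nucleus
DNAJB6	5.614	peripheral	Nucleus
GBX2	2.59	peripheral	Nucleus
KLF6	2.865	peripheral	Nucleus
MAFG	-2.632	peripheral	Nucleus
MTDH	-2.544	peripheral	Cytoplasm
PA2G4	-5.783	peripheral	Nucleus
RSF1	-2.618	peripheral	Nucleus
TBL1XR1	-2.134	peripheral	Nucleus
ZMYND11	-2.211	peripheral	Nucleus
ZNF148	2.114	peripheral	Nucleus
ACIN1	-2.515	peripheral	Nucleus
CYP1B1	4.808	peripheral	Cytoplasm
DPYD	2.292	peripheral	Cytoplasm
MFN1	2.304	peripheral	Cytoplasm
MX1	7.326	peripheral	Cytoplasm
SETD8	-3.93	peripheral	Nucleus
TTLL1	2.284	peripheral	Extracellular Space
ACVR1C	-9.107	peripheral	Plasma Membrane
CARD11	2.892	peripheral	Cytoplasm
CDK11A	-14.872	peripheral	Nucleus
CDK19	-2.191	peripheral	Nucleus
PIK3CD	-2.113	peripheral	Cytoplasm
PRKAA2	-2.546	peripheral	Cytoplasm
SRPK2	-23.589	peripheral	Nucleus
PPP3CB	2.1	peripheral	Plasma Membrane
PTPRF	-20.492	peripheral	Plasma Membrane
IL6ST	-3.283	peripheral	Plasma Membrane
PRLR	-3.192	peripheral	Plasma Membrane
LCN2	3.895	peripheral	Extracellular Space
RASA1	-2.105	peripheral	Cytoplasm
TIMP1	2.101	peripheral	Extracellular Space
EIF5B	-8.766	peripheral	Cytoplasm
AHI1	-2.897	peripheral	Cytoplasm
CDT1	-2.295	peripheral	Nucleus
CISD2	-19.012	peripheral	Cytoplasm
GADD45G	-2.384	peripheral	Nucleus
HLA-A	3.657	peripheral	Plasma Membrane
LINGO1	-2.173	peripheral	Plasma Membrane
MAFB	-2.018	peripheral	Nucleus
PHLDA1	2.16	peripheral	Cytoplasm
PMEPA1	-2.937	peripheral	Plasma Membrane
PSIP1	2.113	peripheral	Nucleus
RAD23B	-2.217	peripheral	Nucleus
RASSF4	2.106	peripheral	Other
RDX	-5.274	peripheral	Cytoplasm
Serbp1	-2.059	peripheral	Cytoplasm
SERPINA3	2.509	peripheral	Extracellular Space
AURKAIP1	-2.023	orphan	Nucleus
CP	8.477	orphan	Extracellular Space
EHD4	-2.056	orphan	Plasma Membrane
ENTPD5	-2.055	orphan	Cytoplasm
KIF3A	-11.754	orphan	Cytoplasm
NDUFAB1	-2.028	orphan	Cytoplasm
PDE4B	2.359	orphan	Cytoplasm
RND3	-2.971	orphan	Cytoplasm
SDC1	2.566	orphan	Plasma Membrane
SRXN1	2.402	orphan	Cytoplasm
ATRX	-5.964	orphan	Nucleus
KLF13	-4.582	orphan	Nucleus
NAA15	-3.751	orphan	Nucleus
KCND2	-7.585	orphan	Plasma Membrane
KCNN4	-9.429	orphan	Plasma Membrane
CAMK2N1	-23.824	orphan	Plasma Membrane
TRPM7	2.226	orphan	Plasma Membrane
ATP2B2	2.276	orphan	Plasma Membrane
TPR	-2.728	orphan	Nucleus
FGL2	4.017	orphan	Extracellular Space
EIF3C	-9.072	orphan	Other
Brd4	-15.202	orphan	Nucleus
CCDC86	-2.149	orphan	Nucleus
CD68	2.007	orphan	Plasma Membrane
CDH13	-2.692	orphan	Plasma Membrane
CMIP	-13.763	orphan	Cytoplasm
Ctdspl	-36.886	orphan	Cytoplasm
KIFAP3	-7.831	orphan	Cytoplasm
LCP1	2.799	orphan	Cytoplasm
LSP1	2.14	orphan	Cytoplasm
Nos1ap	-5.717	orphan	Other
PALLD	-5.086	orphan	Plasma Membrane
Rbm25	-16.213	orphan	Nucleus
Slpi	3.119	orphan	Cytoplasm
THOC2	-4.886	orphan	Nucleus
Tpm3	-2.715	orphan	Cytoplasm
TRIM54	-2.032	orphan	Cytoplasm
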