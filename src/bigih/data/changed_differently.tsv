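gene	fold_change_ipsi	fold_change_contra	ratio	compartment
SPP1	37.905	2.370	15.994	Extracellular Space
TIMP1	38.486	2.101	18.318	Extracellular Space
CP	27.838	8.477	3.284	Extracellular Space
FGL2	16.793	4.017	4.180	Extracellular Space
LCN2	71.824	3.895	18.440	Extracellular Space
SERPINA3	58.488	2.509	23.311	Extracellular Space
CD44	15.558	2.399	6.485	Plasma Membrane
EHD4	2.361	-2.056	4.854	Plasma Membrane
SDC1	13.681	2.566	5.332	Plasma Membrane
KCND2	-2.792	-7.585	2.717	Plasma Membrane
KCNN4	3.088	-9.429	29.117	Plasma Membrane
CAMK2N1	-11.813	-23.824	2.017	Plasma Membrane
EGFR	6.773	2.374	2.853	Plasma Membrane
PTPRF	-6.365	-20.492	3.219	Plasma Membrane
IL6ST	2.307	-3.283	7.574	Plasma Membrane
CD68	4.365	2.007	2.175	Plasma Membrane
HLA-A	9.296	3.657	2.542	Plasma Membrane
PMEPA1	2.682	-2.937	7.877	Plasma Membrane
CYP1B1	10.998	4.808	2.287	Cytoplasm
KIF3A	-5.083	-11.754	2.312	Cytoplasm
MX1	28.177	7.326	3.846	Cytoplasm
PDE4B	5.602	2.359	2.375	Cytoplasm
RND3	2.864	-2.971	8.509	Cytoplasm
SRXN1	6.306	2.402	2.625	Cytoplasm
CARD11	7.343	2.892	2.539	Cytoplasm
CSNK2A1	2.992	-2.750	8.228	Cytoplasm
EIF5B	-3.044	-8.766	2.880	Cytoplasm
RASA1	2.392	-2.105	5.035	Cytoplasm
AHI1	2.243	-2.897	6.498	Cytoplasm
CISD2	-7.833	-19.012	2.427	Cytoplasm
CMIP	-3.778	-13.763	3.643	Cytoplasm
Ctdspl	-7.271	-36.886	5.073	Cytoplasm
HSPB1	46.922	2.639	17.780	Cytoplasm
KIFAP3	-2.281	-7.831	3.433	Cytoplasm
LCP1	6.082	2.799	2.173	Cytoplasm
LSP1	11.716	2.140	5.475	Cytoplasm
PHLDA1	5.129	2.160	2.375	Cytoplasm
RDX	4.828	-5.274	25.463	Cytoplasm
Slpi	82.908	3.119	26.582	Cytoplasm
Tpm3	2.592	-2.715	7.037	Cytoplasm
TRIM54	-4.426	-2.032	-2.178	Cytoplasm
SETD8	2.029	-3.930	7.974	Nucleus
TOP2A	2.260	-2.406	5.438	Nucleus
CDK11A	-4.290	-14.872	3.467	Nucleus
GSK3B	-2.733	-6.635	2.428	Nucleus
SRPK2	-5.614	-23.589	4.202	Nucleus
THRA	-2.799	-11.518	4.115	Nucleus
ATRX	2.091	-5.964	12.471	Nucleus
BTG2	-2.220	-5.803	2.614	Nucleus
CCAR1	-2.943	-11.648	3.958	Nucleus
CCND1	2.152	-2.027	4.362	Nucleus
CEBPD	11.271	2.037	5.533	Nucleus
DEK	-3.006	-7.352	2.446	Nucleus
DNAJB6	-4.383	5.614	-24.606	Nucleus
KLF13	-2.006	-4.582	2.284	Nucleus
KLF6	6.003	2.865	2.095	Nucleus
NAA15	3.605	-3.751	13.522	Nucleus
NFIX	-2.548	-8.112	3.184	Nucleus
PA2G4	-2.702	-5.783	2.140	Nucleus
SMARCA4	2.521	-7.712	19.442	Nucleus
STAT3	4.219	-3.771	15.910	Nucleus
TBL1XR1	2.587	-2.134	5.521	Nucleus
TCF4	-2.216	-4.625	2.087	Nucleus
TPR	2.212	-2.728	6.034	Nucleus
Brd4	-3.528	-15.202	4.309	Nucleus
CDT1	3.098	-2.295	7.110	Nucleus
GADD45G	3.191	-2.384	7.607	Nucleus
PSIP1	-2.663	2.113	-5.627	Nucleus
Rbm25	-5.547	-16.213	2.923	Nucleus
THOC2	2.119	-4.886	10.353	Nucleus
EIF3C	-4.369	-9.072	2.076	Unknown
Nos1ap	-2.698	-5.717	2.119	Unknown
RASSF4	4.289	2.106	2.037	Unknown
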