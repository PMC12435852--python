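DZ	synthetic stand-in for the 169-gene dark-zone spatial signature	AICDA	CXCR4	FOXO1	BACH2	MKI67	PLK1	PLK4	EZH2	TOP2A	BIRC5	CCNB1	CCNB2	CCNA2	CDK1	CDC20	CDC45	CDC6	CDT1	AURKA	AURKB	BUB1	BUB1B	KIF11	KIF23	KIF2C	CENPA	CENPE	CENPF	NUSAP1	TPX2	UBE2C	PTTG1	MAD2L1	NDC80	SPC25	MCM2	MCM3	MCM4	MCM5	MCM6	MCM7	PCNA	POLA1	POLE	POLD1	LIG1	FEN1	RRM1	RRM2	TYMS	TK1	DHFR	GINS1	GINS2	ORC1	ORC6	E2F1	E2F2	MYBL2	FOXM1	ATR	CHEK1	CLSPN	RAD51	BRCA1	BRCA2	FANCI	FANCD2	EXO1	BLM	RPA3	H2AFX	TOPBP1	WEE1	TTK	ESPL1	SGO1	ASPM	DLGAP5	HMMR	PRC1	ANLN	TROAP	KIF15	KIF4A	MELK	TCF19	ZWINT	RACGAP1	ECT2	STMN1	TUBB	TUBA1B	HMGB2	HMGB1	NASP	DEK	SMC2	SMC4	NCAPG	NCAPH	SYNDZ001	SYNDZ002	SYNDZ003	SYNDZ004	SYNDZ005	SYNDZ006	SYNDZ007	SYNDZ008	SYNDZ009	SYNDZ010	SYNDZ011	SYNDZ012	SYNDZ013	SYNDZ014	SYNDZ015	SYNDZ016	SYNDZ017	SYNDZ018	SYNDZ019	SYNDZ020	SYNDZ021	SYNDZ022	SYNDZ023	SYNDZ024	SYNDZ025	SYNDZ026	SYNDZ027	SYNDZ028	SYNDZ029	SYNDZ030	SYNDZ031	SYNDZ032	SYNDZ033	SYNDZ034	SYNDZ035	SYNDZ036	SYNDZ037	SYNDZ038	SYNDZ039	SYNDZ040	SYNDZ041	SYNDZ042	SYNDZ043	SYNDZ044	SYNDZ045	SYNDZ046	SYNDZ047	SYNDZ048	SYNDZ049	SYNDZ050	SYNDZ051	SYNDZ052	SYNDZ053	SYNDZ054	SYNDZ055	SYNDZ056	SYNDZ057	SYNDZ058	SYNDZ059	SYNDZ060	SYNDZ061	SYNDZ062	SYNDZ063	SYNDZ064	SYNDZ065	SYNDZ066	SYNDZ067	SYNDZ068
LZ	synthetic stand-in for the 201-gene light-zone spatial signature	CD83	CD86	CD40	CD69	CD80	EGR1	EGR2	EGR3	NR4A1	NR4A2	NR4A3	NFKB1	NFKB2	RELB	REL	JUNB	FOS	FOSB	JUN	DUSP1	DUSP2	IER2	KLF6	MYC	BCL2A1	TRAF1	BIRC3	ICAM1	SLAMF1	SEMA7A	CCND2	CD58	CD74	HLA-A	HLA-B	HLA-C	HLA-E	HLA-F	HLA-DRA	HLA-DRB1	HLA-DPA1	HLA-DPB1	HLA-DQA1	HLA-DQB1	HLA-DMA	HLA-DMB	B2M	CIITA	BATF	BCL2	BCL6	SLAMF6	TNFRSF13B	CD3D	CD3E	CD3G	CD2	CD28	ICOS	PDCD1	CTLA4	IL21	IL21R	CXCL13	CXCR5	CCL19	CCL21	CR1	CR2	FCER2	FDCSP	CLU	LTB	TNF	LTA	CD4	IL7R	CCR7	SELL	TNFRSF4	TNFRSF18	FOXP3	IL2RA	GPR183	S1PR2	P2RY8	RGS13	RGS1	SERPINA9	LMO2	MEF2B	POU2AF1	PRDM1	IRF4	XBP1	CD38	CD27	PRKCB	SYK	BLNK	PLCG2	SYNLZ001	SYNLZ002	SYNLZ003	SYNLZ004	SYNLZ005	SYNLZ006	SYNLZ007	SYNLZ008	SYNLZ009	SYNLZ010	SYNLZ011	SYNLZ012	SYNLZ013	SYNLZ014	SYNLZ015	SYNLZ016	SYNLZ017	SYNLZ018	SYNLZ019	SYNLZ020	SYNLZ021	SYNLZ022	SYNLZ023	SYNLZ024	SYNLZ025	SYNLZ026	SYNLZ027	SYNLZ028	SYNLZ029	SYNLZ030	SYNLZ031	SYNLZ032	SYNLZ033	SYNLZ034	SYNLZ035	SYNLZ036	SYNLZ037	SYNLZ038	SYNLZ039	SYNLZ040	SYNLZ041	SYNLZ042	SYNLZ043	SYNLZ044	SYNLZ045	SYNLZ046	SYNLZ047	SYNLZ048	SYNLZ049	SYNLZ050	SYNLZ051	SYNLZ052	SYNLZ053	SYNLZ054	SYNLZ055	SYNLZ056	SYNLZ057	SYNLZ058	SYNLZ059	SYNLZ060	SYNLZ061	SYNLZ062	SYNLZ063	SYNLZ064	SYNLZ065	SYNLZ066	SYNLZ067	SYNLZ068	SYNLZ069	SYNLZ070	SYNLZ071	SYNLZ072	SYNLZ073	SYNLZ074	SYNLZ075	SYNLZ076	SYNLZ077	SYNLZ078	SYNLZ079	SYNLZ080	SYNLZ081	SYNLZ082	SYNLZ083	SYNLZ084	SYNLZ085	SYNLZ086	SYNLZ087	SYNLZ088	SYNLZ089	SYNLZ090	SYNLZ091	SYNLZ092	SYNLZ093	SYNLZ094	SYNLZ095	SYNLZ096	SYNLZ097	SYNLZ098	SYNLZ099	SYNLZ100
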