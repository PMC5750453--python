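LOCUS	GWAS_SNP	EQTL	R2	GENE	P	STUDY	TISSUE	OTHER_STUDIES
1	rs662064	rs668805	1.0	PEX14	1.2E-019	Zeller	Monocytes	Yes
1	rs662064	rs12028449	0.81	DFFA	1.2E-012	Westra	Whole blood	No
2	rs4129267	rs4537545	0.93	IL6R	2.0E-029	Westra	Whole blood	Yes
3	rs4233366	rs4233366	1.0	FCER1G	5.0E-215	Jansen	Whole blood	Yes
3	rs4233366	rs4233366	1.0	B4GALT3	1.5E-026	GTEx	Fibroblasts	No
3	rs4233366	rs4233366	1.0	ADAMTS4	1.8E-024	GTEx	Fibroblasts	No
3	rs4233366	rs4233366	1.0	PPOX	6.2E-012	GTEx	Fibroblasts	No
3	rs4233366	rs4233366	1.0	F11R	3.4E-011	Fehrmann	Whole blood	No
3	rs4233366	rs4233366	1.0	USF1	3.4E-011	Fehrmann	Whole blood	Yes
3	rs4233366	rs2070901	0.96	TOMM40L	7.3E-010	Naranbhai	Neutrophils	No
4	rs1723018	rs2988279	0.93	CD247	3.1E-062	Zhernakova	Whole blood	Yes
5	rs6691738	rs7553711	0.99	TNFSF4	1.9E-035	Yao	Whole blood	No
7	rs6683383	rs6683383	1.0	ADORA1	6.0E-096	Zeller	Monocytes	Yes
7	rs6683383	rs3766568	1.0	CHIT1	6.6E-030	Zhernakova	Whole blood	Yes
7	rs6683383	rs10920570	1.0	MYBPH	5.2E-018	Zeller	Monocytes	Yes
7	rs6683383	rs17464408	0.99	RP11-335O13.7	8.1E-021	Zhernakova	Whole blood	Yes
7	rs6683383	rs7555556	0.98	PPFIA4	8.1E-162	Zhernakova	Whole blood	Yes
9	rs10173081	rs3771180	1.0	MFSD9	1.7E-015	Yao	Whole blood	No
9	rs10173081	rs11674302	0.8	IL18RAP	7.9E-091	Yao	Whole blood	No
9	rs10173081	rs10189629	0.8	IL1RL1	3.0E-012	Zhernakova	Whole blood	No
9	rs3771166	rs11688559	1.0	AC007278.3	4.3E-249	Zhernakova	Whole blood	No
12	rs4833095	rs12233670	0.98	TLR1	2.8E-057	Battle	Whole blood	Yes
14	rs1438673	rs7723819	0.86	WDR36	2.4E-031	Yao	Whole blood	No
14	rs1438673	rs10073816	0.85	TSLP	3.3E-012	Zhernakova	Whole blood	Yes
14	rs1438673	rs2289277	0.84	CTC-551A13.2	7.0E-029	Zhernakova	Whole blood	Yes
14	rs1438673	rs10051830	0.82	CAMK4	1.8E-016	Yao	Whole blood	No
15	rs2244012	rs2246176	0.99	SLC22A5	8.7E-014	Westra	Whole blood	No
16	rs166079	rs12655465	1.0	NDFIP1	6.8E-115	Zhernakova	Whole blood	Yes
17	rs2428494	rs2428494	1.0	MICB	2.3E-011	Walsh	Whole blood	No
18	rs9268516	rs9268400	0.99	HLA-DRB6	6.2E-011	Dinarzo	Whole blood	No
18	rs9272346	rs9272346	1.0	HLA-DQB1	4.9E-324	Zeller	Monocytes	Yes
18	rs9272346	rs9272346	1.0	HLA-DRB5	2.1E-121	Westra	Whole blood	Yes
18	rs9272346	rs9272346	1.0	TAP2	4.1E-011	Westra	Whole blood	No
18	rs9273373	rs1063355	0.99	HLA-DQA1	3.6E-154	Raj	Monocytes	Yes
18	rs9273373	rs3134993	0.95	HLA-DQB1-AS1	5.6E-058	GTEx	Lung	No
18	rs9273373	rs1063349	0.92	HLA-DQB2	1.1E-089	Geuvadis	LCLs	No
18	rs9273373	rs9272545	0.87	HLA-DQA2	1.1E-022	Quach	Monocytes	Yes
27	rs10519068	rs11633029	0.86	RP11-554D20.1	3.7E-017	Zhernakova	Whole blood	Yes
28	rs56375023	rs17293632	0.98	AAGAB	1.7E-013	Zhernakova	Whole blood	Yes
30	rs11078927	rs12946510	0.8	GSDMA	2.2E-016	Hao	Lung	No
30	rs11655198	rs9903250	1.0	RP11-94L15.2	5.2E-064	Zhernakova	Whole blood	Yes
30	rs11655198	rs11655198	1.0	ORMDL3	7.4E-041	Kasela	CD8 T-cells	Yes
30	rs11655198	rs2305479	0.97	IKZF3	5.6E-021	Zhernakova	Whole blood	Yes
30	rs11655198	rs8067378	0.96	ZPBP2	2.4E-017	Grundberg	LCLs	Yes
30	rs2271308	rs1053651	0.99	STARD3	1.4E-016	Fairfax	Monocytes	Yes
30	rs2271308	rs1053651	0.99	PGAP3	9.9E-014	Yao	Whole blood	No
30	rs2271308	rs4795388	0.83	PPP1R1B	4.1E-010	Andiappan	Neutrophils	No
30	rs4794820	rs4794820	1.0	GSDMB	1.1E-296	Zhernakova	Whole blood	Yes
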