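INDEX	SNP	CHR	BP	CONTEXT	EA	MAF	OR	P	H2_PCT_PRINTED
1	rs662064	1	10557251	[PEX14]	C	0.31	1.04	9.7E-006	0.02
2	rs4129267	1	154426264	[IL6R]	T	0.41	1.03	5.8E-006	0.02
3	rs4233366	1	161159147	PPOX-[]-ADAMTS4	T	0.27	1.04	4.7E-007	0.02
4	rs1723018	1	167433420	[CD247]	G	0.41	0.95	5.7E-012	0.04
5	rs6691738	1	173152036	TNFSF18-[]-TNFSF4	G	0.29	1.04	5.8E-007	0.02
6	rs2786098	1	197325908	[CRB1]	G	0.22	1.00	0.5827	0.00
7	rs6683383	1	203100504	[ADORA1]	A	0.33	0.95	5.9E-011	0.04
8	rs13412757	2	8458080	[LINC00299]	A	0.34	0.94	1.8E-013	0.05
9	rs3771166	2	102986222	[IL18R1]	A	0.38	0.90	7.4E-040	0.15
10	rs34290285	2	242698640	[D2HGDH]	A	0.26	0.89	1.5E-039	0.15
11	rs73196739	3	188402471	[LPP]	T	0.17	0.94	4.1E-010	0.03
12	rs4833095	4	38799710	[TLR1]	C	0.21	0.92	1.3E-017	0.06
13	rs1588265	5	59369794	[PDE4D]	G	0.31	1.01	0.2859	0.00
14	rs1837253	5	110401872	SLC25A46-[]-TSLP	C	0.26	1.12	3.4E-041	0.16
15	rs6871536	5	131969874	[RAD50]	C	0.19	1.10	1.0E-024	0.09
16	rs166079	5	141528959	[NDFIP1]	T	0.38	1.04	1.8E-008	0.03
17	rs2428494	6	31322197	[HLA-B]	A	0.47	1.12	6.1E-055	0.20
18	rs17843604	6	32620283	HLA-DQA1-[]-HLA-DQB1	T	0.42	1.18	1.9E-105	0.41
19	rs58521088	6	90985198	[BACH2]	T	0.35	0.93	2.5E-021	0.08
20	rs6967330	7	105658451	[CDHR3]	A	0.17	1.01	0.2233	0.00
21	rs7009110	8	81291879	MIR5708-[]-ZBTB10	C	0.38	0.94	9.6E-018	0.06
22	rs1342326	9	6190076	RANBP6-[]-IL33	C	0.16	1.15	6.4E-048	0.17
23	rs12413578	10	9049253	GATA3-[]-SFTA1P	T	0.11	0.86	1.0E-033	0.13
24	rs7130588	11	76270683	WNT11-[]-LRRC32	G	0.36	1.10	8.9E-033	0.12
25	rs3001426	12	57509055	[STAT6]	C	0.45	1.07	1.4E-021	0.08
26	rs3784099	14	68749927	[RAD51B]	A	0.28	1.06	1.4E-012	0.04
27	rs11071559	15	61069988	[RORA]	T	0.13	0.91	7.3E-017	0.06
28	rs744910	15	67446785	[SMAD3]	A	0.48	0.95	3.5E-014	0.05
29	rs62026376	16	11228712	[CLEC16A]	T	0.25	0.92	7.7E-023	0.08
30	rs7216389	17	38069949	[GSDMB]	T	0.48	1.11	1.7E-044	0.16
31	rs2284033	22	37534034	[IL2RB]	A	0.43	0.97	4.2E-004	0.01
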