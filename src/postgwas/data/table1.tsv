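INDEX	SNP	CHR	BP	CONTEXT	EA	OR	P	PMID	YEAR	CORRELATED_IN_OTHER_GWAS
1	rs662064	1	10557251	[PEX14]	T	0.94	3.2E-08	27182965	2016	No
2	rs4129267	1	154426264	[IL6R]	T	1.09	2.4E-08	21907864	2011	No
3	rs4233366	1	161159147	PPOX-[]-ADAMTS4	T	1.09	4.8E-15	27182965	2016	No
4	rs1723018	1	167433420	[CD247]	G	0.95	1.4E-08	27182965	2016	No
5	rs6691738	1	173152036	TNFSF18-[]-TNFSF4	T	0.94	2.9E-08	27182965	2016	No
6	rs2786098	1	197325908	[CRB1]	A	0.63	8.6E-09	20032318	2009	No
7	rs6683383	1	203100504	[ADORA1]	T	1.06	1.1E-08	27182965	2016	No
8	rs13412757	2	8458080	[LINC00299]	G	1.06	1.3E-08	27182965	2016	No
9	rs3771166	2	102986222	[IL18R1]	A	0.87	3.4E-09	20860503	2010	Yes
10	rs34290285	2	242698640	[D2HGDH]	G	1.11	1.8E-15	27182965	2016	No
11	rs73196739	3	188402471	[LPP]	T	0.92	6.5E-09	27182965	2016	No
12	rs4833095	4	38799710	[TLR1]	T	1.20	5.0E-12	24388013	2013	Yes
13	rs1588265	5	59369794	[PDE4D]	G	0.60	2.5E-08	19426955	2009	No
14	rs1837253	5	110401872	SLC25A46-[]-TSLP	C	1.19	7.3E-10	21804549	2011	Yes
15	rs6871536	5	131969874	[RAD50]	C	1.14	2.4E-09	21907864	2011	Yes
16	rs200634877	5	141529762	[NDFIP1]	I	0.94	2.5E-08	27182965	2016	No
17	rs2428494	6	31322197	[HLA-B]	T	0.92	1.4E-16	27182965	2016	No
18	rs17843604	6	32728261	HLA-DQA1-[]-HLA-DQB1	T	1.16	1.7E-10	20860503	2010	Yes
19	rs58521088	6	90985198	[BACH2]	T	0.93	7.1E-11	27182965	2016	No
20	rs6967330	7	105658451	[CDHR3]	A	1.45	1.4E-08	24241537	2013	Yes
21	rs7009110	8	81291879	MIR5708-[]-ZBTB10	T	1.14	4.0E-09	24388013	2013	Yes
22	rs1342326	9	6190076	RANBP6-[]-IL33	C	1.20	9.2E-10	20860503	2010	Yes
23	rs12413578	10	9049253	GATA3-[]-SFTA1P	T	0.89	8.1E-12	27182965	2016	No
24	rs7130588	11	76270683	WNT11-[]-LRRC32	G	1.09	1.8E-08	21907864	2011	Yes
25	rs3001426	12	57509055	[STAT6]	T	0.94	1.4E-10	27182965	2016	No
26	rs3784099	14	68749927	[RAD51B]	G	0.94	1.6E-08	27182965	2016	No
27	rs11071559	15	61069988	[RORA]	T	0.85	3.8E-09	21907864	2011	Yes
28	rs744910	15	67446785	[SMAD3]	A	0.89	3.9E-09	20860503	2010	Yes
29	rs62026376	16	11228712	[CLEC16A]	C	1.17	1.0E-08	24388013	2013	Yes
30	rs7216389	17	38069949	[GSDMB]	T	1.45	9.0E-11	17611496	2007	Yes
31	rs2284033	22	37534034	[IL2RB]	A	0.89	1.2E-08	20860503	2010	No
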