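GENE	N_BEFORE	N_SINCE	GROUP_PRINTED
TSLP	21	814	1
IL1RL1	16	260	1
TNFSF4	9	50	1
TLR1	8	43	1
HLA-DQB1	30	31	1
HLA-DQB2	28	30	1
HLA-DQA1	13	13	1
ADORA1	12	5	1
TAP2	9	2	1
ORMDL3	0	115	2
GSDMB	0	57	2
ZPBP2	0	18	2
IL6R	2	15	2
GSDMA	0	15	2
CHIT1	2	14	2
IKZF3	0	11	2
FCER1G	1	9	2
SLC22A5	0	7	2
WDR36	0	6	2
IL18RAP	1	5	2
HLA-DQA2	0	5	2
NDFIP1	0	5	2
F11R	2	3	3
HLA-DRB5	1	2	3
MICB	1	2	3
STARD3	1	2	3
PGAP3	0	2	3
PPP1R1B	0	2	3
AAGAB	2	1	3
USF1	2	1	3
ADAMTS4	0	1	3
B4GALT3	0	1	3
DFFA	0	1	3
PAG1	0	1	3
AC007278.3	0	0	3
CAMK4	0	0	3
CD247	0	0	3
CTC-551A13.2	0	0	3
HLA-DQB1-AS1	0	0	3
HLA-DRB6	0	0	3
MFSD9	0	0	3
MYBPH	0	0	3
PEX14	0	0	3
PPFIA4	0	0	3
PPOX	0	0	3
RP11-335O13.7	0	0	3
RP11-554D20.1	0	0	3
RP11-94L15.2	0	0	3
TOMM40L	0	0	3
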