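DISEASE	N_CASES	N_CONTROLS	N_TOTAL	N_ASSOC	PMID	PREVALENCE	NCP_PRINTED
Atopic dermatitis	18900	84166	103066	21	26482879	0.20	24
Asthma	28399	128843	157242	27	27182965	0.15	40
Type 2 diabetes	26676	132532	159208	42	28566273	0.05	52
Schizophrenia	36989	113075	150064	128	25056061	0.01	102
Rheumatoid arthritis	29880	73758	103638	101	24390342	0.01	77
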