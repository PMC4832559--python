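site_id	gene	chrom	n_AA	n_AB	n_BB	n_breeds	private	assoc_p_nominal	assoc_m
g.26775767G>C	NEURL1	ECA1	272	37	9	7	0
g.77472655G>C	KDR	ECA3	243	73	4	11	0
g.74610774C>T	CFTR	ECA4	283	1	0	2	0
g.56937215C>T	OVGP1	ECA5	208	26	0	3	0
g.45985131A>G	FBXO43	ECA9	306	10	0	4	0
g.82699661C>T	TSSK6	ECA9	290	21	0	8	0
g.7083659A>T	SLC9A3R1	ECA11	164	128	30	12	0
g.40694339G>A	PKD1	ECA13	317	4	0	2	0
g.6704968C>T	GHRL	ECA16	314	6	1	5	0
g.19034281C>T	FOXP1	ECA16	283	33	0	11	0
g.32635273T>C	BTNL2	ECA20	200	55	73	7	0
g.35255390T>C	TCP11	ECA20	310	7	0	2	0
g.4323852G>A	SPATA31E1	ECA25	318	3	0	3	0
g.37453246G>C	NOTCH1	ECA25	304	7	0	4	0
g.37455302G>A	NOTCH1	ECA25	247	74	7	9	0	0.00003	15
g.79813487A>T	ENSECAG00000020135	ECA3	74	0	0	1	1
g.25184403G>C	ENSECAG00000021286	ECA7	74	0	0	1	1
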