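nucleotide	gene_function	position	percent	cluster	gene	codon_from	codon_to	aa_from	aa_to	class_from	class_to
C	Accessory	101605	37.55	4	Ac126/chitinase	TCA	GCA	S	A	NP	NoPolarity
C	Accessory	101638	38.05	4	Ac126/chitinase	AAA	GAA	K	E	BP	AP
T	Accessory	101647	38.08	4	Ac126/chitinase	CCC	ACC	P	T	NoPolarity	NP
G	Accessory	101716	40.18	4	Ac126/chitinase	GGT	CGT	G	R	NoPolarity	BP
G	Accessory	101793	36.25	4	Ac126/chitinase	AGA	AGC	R	S	BP	NP
A	Accessory	101851	35.62	4	Ac126/chitinase	GGC	TGC	G	C	NoPolarity	NP
C	Accessory	101884	37.25	4	Ac126/chitinase	TCA	GCA	S	A	NP	NoPolarity
T	Host interaction	110347	15.71	3	Ac134/p94	CGC	AGC	R	S	BP	NP
G	BV specific	14832	19.28	3	Ac23/f-protein	ACA	GCA	T	A	NP	NoPolarity
T	BV specific	14833	18.27	3	Ac23/f-protein	ACA	ATA	T	I	NP	NoPolarity
A	BV specific	103990	21.18	3	Ac128/gp64	TCG	TTG	S	L	NP	NoPolarity
A	ODV specific	2	36.71	4	Ac8/polyhedrin	ATG	AAG	M	K	NoPolarity	BP
A	ODV specific	4	38.94	4	Ac8/polyhedrin	CCG	ACG	P	T	NoPolarity	NP
T	ODV specific	4	32.48	4	Ac8/polyhedrin	CCG	TCG	P	S	NoPolarity	NP
A	ODV specific	5	12.99	3	Ac8/polyhedrin	CCG	CAG	P	Q	NoPolarity	NP
A	ODV specific	13917	14.02	3	Ac22/pif-2	GGG	AGG	G	R	NoPolarity	BP
A	ODV specific	33571	30.25	4	Ac46/odv-e66	GCC	ACC	A	T	NoPolarity	NP
G	ODV specific	64772	22.98	3	Ac83/vp91	ACC	GCC	T	A	NP	NoPolarity
A	ODV specific	70144	13.09	3	Ac88/cg30	CAA	AAA	Q	K	NP	BP
A	ODV specific	70234	13.58	3	Ac88/cg30	GCC	TCC	A	S	NoPolarity	NP
A	ODV specific	70268	13.58	3	Ac88/cg30	ACA	ATA	T	I	NP	NoPolarity
A	ODV specific	70381	13.68	3	Ac88/cg30	GAC	TAC	D	Y	AP	NP
T	ODV specific	70399	13.78	3	Ac88/cg30	GCG	ACG	A	T	NoPolarity	NP
G	ODV specific	94932	23.84	3	Ac115/pif-3	GGT	CGT	G	R	NoPolarity	BP
C	ODV specific	97271	40.46	4	Ac119/pif-1	TCG	CCG	S	P	NP	NoPolarity
T	PA	71103	14.86	3	Ac89/vp39	CGC	AGC	R	S	BP	NP
C	PA	74220	21.51	3	Ac92/p33	AAA	GAA	K	E	BP	AP
C	PA	74391	17.50	3	Ac92/p33	AAA	GAA	K	E	BP	AP
A	PA	74421	32.40	4	Ac92/p33	CAC	TAC	H	Y	BP	NP
G	PA	84226	30.75	4	Ac103/p45	ACT	CCT	T	P	NP	NoPolarity
T	PA	91064	13.25	3	Ac109/odv-ec43	GAG	AAG	E	K	AP	BP
A	Replication	29534	13.78	3	Ac42/gta	GCG	ACG	A	T	NoPolarity	NP
A	Transcription	28878	30.16	4	Ac41/lef-12	GAC	AAC	D	N	AP	NP
G	Transcription	29337	18.47	3	Ac41/lef-12	ACA	GCA	T	A	NP	NoPolarity
T	Transcription	29346	18.55	3	Ac41/lef-12	CCA	TCA	P	S	NoPolarity	NP
A	Transcription	36848	17.11	3	Ac50/lef-8	CAC	TAC	H	Y	BP	NP
G	Transcription	45913	26.33	3	Ac62/lef-9	AAA	GAA	K	E	BP	AP
C	Transcription	68643	24.53	3	Ac86/pnk/pnl	ACA	GCA	T	A	NP	NoPolarity
T	Transcription	73303	16.73	3	Ac90/lef-4	TCG	TTG	S	L	NP	NoPolarity
T	Transcription	73356	16.95	3	Ac90/lef-4	CCG	TCG	P	S	NoPolarity	NP
G	Unknown	23830	24.44	3	Ac34	AAT	CAT	N	H	NP	BP
G	Unknown	23932	22.47	3	Ac34	TAT	CAT	Y	H	NP	BP
T	Unknown	23938	22.88	3	Ac34	GAG	AAG	E	K	AP	BP
C	Unknown	24013	22.45	3	Ac34	CGC	GGC	R	G	BP	NoPolarity
G	Unknown	24025	22.20	3	Ac34	AAT	CAT	N	H	NP	BP
G	Unknown	24112	24.62	3	Ac34	TAT	CAT	Y	H	NP	BP
G	Unknown	24205	24.73	3	Ac34	GGG	CGG	G	R	NoPolarity	BP
G	Unknown	24226	24.57	3	Ac34	GGG	CGG	G	R	NoPolarity	BP
G	Unknown	24263	24.26	3	Ac34	GAT	GCT	D	A	AP	NoPolarity
C	Unknown	24267	24.15	3	Ac34	AAT	AAG	N	K	NP	BP
T	Unknown	24277	24.28	3	Ac34	CAG	AAG	Q	K	NP	BP
C	Unknown	41973	34.83	4	Ac55	TTG	TCG	L	S	NoPolarity	NP
A	Unknown	73784	25.98	3	Ac91	CCA	TCA	P	S	NoPolarity	NP
T	Unknown	74061	15.53	3	Ac91	TTA	TAA	L	*	NoPolarity	None
A	Unknown	89718	14.28	3	Ac106/107	CCA	ACA	P	T	NoPolarity	NP
G	Unknown	93822	20.30	3	Ac114	AAT	CAT	N	H	NP	BP
C	Unknown	133289	37.26	4	Ac7/orf603	CTG	CGG	L	R	NoPolarity	BP
T	Unknown	133648	37.68	4	Ac7/orf603	CCA	ACA	P	T	NoPolarity	NP
G	Unknown	133708	26.94	3	Ac7/orf603	AAC	CAC	N	H	NP	BP
C	Unknown	133738	27.70	4	Ac7/orf603	AAG	GAG	K	E	BP	AP
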