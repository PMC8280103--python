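# Published codon counts and RSCU for the 13 protein-coding genes of the
# Exhippolysmata ensirostris mitogenome (GenBank MK681888), invertebrate
# mitochondrial genetic code (translation table 5). RSCU as printed (up to
# 2 dp). Stop codons (UAA/UAG, aa "*") are tallied as their own two-member
# family; the published counting includes all in-frame triplets.
Codon	AA	Count	RSCU
UUU	F	132	1.17
UUC	F	93	0.83
UUA	L	106	1.46
UUG	L	32	0.44
CUU	L	95	1.31
CUC	L	74	1.02
CUA	L	99	1.37
CUG	L	29	0.4
AUU	I	117	1.2
AUC	I	78	0.8
AUA	M	112	1.62
AUG	M	26	0.38
GUU	V	57	1.5
GUC	V	16	0.42
GUA	V	62	1.63
GUG	V	17	0.45
UCU	S	101	1.72
UCC	S	58	0.99
UCA	S	74	1.26
UCG	S	9	0.15
CCU	P	88	1.56
CCC	P	66	1.17
CCA	P	58	1.03
CCG	P	13	0.23
ACU	T	80	1.36
ACC	T	61	1.04
ACA	T	80	1.36
ACG	T	14	0.24
GCU	A	56	1.68
GCC	A	29	0.87
GCA	A	38	1.14
GCG	A	10	0.3
UAU	Y	100	1.27
UAC	Y	58	0.73
UAA	*	99	1.51
UAG	*	32	0.49
CAU	H	74	1.14
CAC	H	56	0.86
CAA	Q	69	1.5
CAG	Q	23	0.5
AAU	N	107	1.06
AAC	N	95	0.94
AAA	K	117	1.36
AAG	K	55	0.64
GAU	D	56	1.26
GAC	D	33	0.74
GAA	E	60	1.38
GAG	E	27	0.62
UGU	C	23	0.84
UGC	C	32	1.16
UGA	W	59	1.4
UGG	W	25	0.6
CGU	R	18	1.09
CGC	R	9	0.55
CGA	R	30	1.82
CGG	R	9	0.55
AGU	S	37	0.63
AGC	S	61	1.04
AGA	S	82	1.4
AGG	S	47	0.8
GGU	G	30	0.84
GGC	G	25	0.7
GGA	G	64	1.79
GGG	G	24	0.67
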