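# IGHG1 allele <-> G1m allele correspondence.
# Determining residues: CH1 positions 103, 120; CH3 positions 12, 14, 101,
# 110, 115, 116.  provisional = allele expected from serology but not yet
# sequenced at the nucleotide level.
ighg1_allele	g1m_allele	isoallotypes	ch1_103	ch1_120	ch3_12	ch3_14	ch3_101	ch3_110	ch3_115	ch3_116	provisional	populations
IGHG1*01	G1m17,1		I	K	D	L	V	A	H	Y	no	Caucasoid,Negroid,Mongoloid
IGHG1*02	G1m17,1		I	K	D	L	V	A	H	Y	no	Caucasoid,Negroid,Mongoloid
IGHG1*05	G1m17,1		I	K	D	L	V	A	H	Y	no	Caucasoid,Negroid,Mongoloid
IGHG1*03	G1m3	nG1m1,nG1m17	I	R	E	M	V	A	H	Y	no	Caucasoid
IGHG1*04	G1m17,1,27		I	K	D	L	I	A	H	Y	no	Negroid
IGHG1*05p	G1m17,1,28		I	K	D	L	V	A	R	Y	yes	Negroid
IGHG1*06p	G1m17,1,27,28		I	K	D	L	I	A	R	Y	yes	Negroid
IGHG1*07p	G1m17,1,2		I	K	D	L	V	G	H	Y	yes	Caucasoid,Mongoloid
IGHG1*08p	G1m3,1	nG1m17	I	R	D	L	V	A	H	Y	yes	Mongoloid
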