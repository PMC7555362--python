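# Kappa-chain (IGKC) Km alleles from the residues at C-DOMAIN positions
# 45.1 and 101.
km_allele	pos45_1	pos101	igkc_alleles
Km3	A	V	IGKC*01,IGKC*02,IGKC*03,IGKC*05
Km1,2	A	L	IGKC*04
Km1	V	L	IGKC*06
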