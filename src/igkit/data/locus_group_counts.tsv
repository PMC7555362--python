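# Numbers of IG genes and alleles per IMGT group, split between the major
# locus (genes that can contribute to chain synthesis) and orphon sets.
locus	group	major_genes	orphon_genes	major_alleles	orphon_alleles
IGH	IGHV	159	26	494	49
IGH	IGHD	27	10	34	10
IGH	IGHJ	9	0	19	0
IGH	IGHC	11	1	91	2
IGK	IGKV	77	32	114	34
IGK	IGKJ	5	0	9	0
IGK	IGKC	1	0	5	0
IGL	IGLV	78	4	144	5
IGL	IGLJ	11	0	10	0
IGL	IGLC	11	3	21	4
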