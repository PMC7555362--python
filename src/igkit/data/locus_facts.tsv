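# Locus-level facts not derivable from the gene tables.
# The IGHM membrane-anchor exon model: exon M1 encodes 39 AA, exon M2
# encodes 2 AA; together the 41 AA anchor region comprises the connecting
# (CO, 13 AA), transmembrane (TM, 27 AA) and cytoplasmic (CY, 1 AA) regions.
key	value
igh_span_kb	1250
igk_span_kb	1820
igl_span_kb	1050
igk_proximal_v_cluster_genes	40
igk_distal_v_cluster_genes	36
ighv_functional_min	38
ighv_functional_max	46
igkv_functional_min	31
igkv_functional_max	35
iglv_functional_min	29
iglv_functional_max	33
ighm_m1_aa	39
ighm_m2_aa	2
ighm_anchor_co_aa	13
ighm_anchor_tm_aa	27
ighm_anchor_cy_aa	1
ighm_secreted_chs_aa	20
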