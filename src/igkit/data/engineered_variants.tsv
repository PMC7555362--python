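# IGHG engineered variants, one row per amino acid change.
# Changes are relative to allele *01 of the gene.  imgt_pos uses dotted
# sub-position notation within the named domain (h = hinge); eu_pos is the
# corresponding Eu number.  An aa value starting with "ins" denotes an
# insertion after imgt_pos.
gene	variant	domain	aa	imgt_pos	eu_pos	properties
IGHG1	IGHG1v1	CH2	P	1.4	233	ADCC reduction
IGHG1	IGHG1v2	CH2	V	1.3	234	ADCC reduction
IGHG1	IGHG1v3	CH2	A	1.2	235	ADCC reduction
IGHG1	IGHG1v4	CH2	A	114	329	ADCC reduction;CDC reduction
IGHG1	IGHG1v5	CH2	W	109	326	ADCC reduction;CDC enhancement
IGHG1	IGHG1v6	CH2	A	85.4	298	ADCC enhancement
IGHG1	IGHG1v6	CH2	A	118	333	ADCC enhancement
IGHG1	IGHG1v6	CH2	A	119	334	ADCC enhancement
IGHG1	IGHG1v7	CH2	D	3	239	ADCC enhancement
IGHG1	IGHG1v7	CH2	E	117	332	ADCC enhancement
IGHG1	IGHG1v8	CH2	D	3	239	ADCC enhancement;CDC reduction
IGHG1	IGHG1v8	CH2	L	115	330	ADCC enhancement;CDC reduction
IGHG1	IGHG1v8	CH2	E	117	332	ADCC enhancement;CDC reduction
IGHG1	IGHG1v9	CH2	L	7	243	ADCC enhancement
IGHG1	IGHG1v9	CH2	P	83	292	ADCC enhancement
IGHG1	IGHG1v9	CH2	L	85.2	300	ADCC enhancement
IGHG1	IGHG1v9	CH2	I	88	305	ADCC enhancement
IGHG1	IGHG1v9	CH3	L	83	396	ADCC enhancement
IGHG1	IGHG1v10	CH2	Y	1.3	234	ADCC enhancement
IGHG1	IGHG1v10	CH2	Q	1.2	235	ADCC enhancement
IGHG1	IGHG1v10	CH2	W	1.1	236	ADCC enhancement
IGHG1	IGHG1v10	CH2	M	3	239	ADCC enhancement
IGHG1	IGHG1v10	CH2	D	30	268	ADCC enhancement
IGHG1	IGHG1v10	CH2	E	34	270	ADCC enhancement
IGHG1	IGHG1v10	CH2	A	85.4	298	ADCC enhancement
IGHG1	IGHG1v11	CH2	E	34	270	ADCC enhancement
IGHG1	IGHG1v11	CH2	D	109	326	ADCC enhancement
IGHG1	IGHG1v11	CH2	M	115	330	ADCC enhancement
IGHG1	IGHG1v11	CH2	E	119	334	ADCC enhancement
IGHG1	IGHG1v12	CH2	A	1.1	236	ADCC enhancement
IGHG1	IGHG1v12	CH2	D	3	239	ADCC enhancement
IGHG1	IGHG1v12	CH2	L	115	330	ADCC enhancement
IGHG1	IGHG1v12	CH2	E	117	332	ADCC enhancement
IGHG1	IGHG1v13	CH2	A	1.1	236	ADCP enhancement
IGHG1	IGHG1v13	CH2	D	3	239	ADCP enhancement
IGHG1	IGHG1v13	CH2	E	117	332	ADCP enhancement
IGHG1	IGHG1v14	CH2	A	1.3	234	ADCC reduction;CDC reduction
IGHG1	IGHG1v14	CH2	A	1.2	235	ADCC reduction;CDC reduction
IGHG1	IGHG1v15	CH2	S	118	333	CDC enhancement
IGHG1	IGHG1v16	CH2	W	109	326	CDC enhancement
IGHG1	IGHG1v16	CH2	S	118	333	CDC enhancement
IGHG1	IGHG1v17	CH2	E	29	267	CDC enhancement
IGHG1	IGHG1v17	CH2	F	30	268	CDC enhancement
IGHG1	IGHG1v17	CH2	T	107	324	CDC enhancement
IGHG1	IGHG1v18	CH3	R	1	345	CDC enhancement;Favors hexamerisation
IGHG1	IGHG1v18	CH3	G	109	430	CDC enhancement;Favors hexamerisation
IGHG1	IGHG1v18	CH3	Y	120	440	CDC enhancement;Favors hexamerisation
IGHG1	IGHG1v19	CH2	A	34	270	CDC reduction
IGHG1	IGHG1v20	CH2	A	105	322	CDC reduction
IGHG1	IGHG1v21	CH2	Y	15.1	252	Half-life increase
IGHG1	IGHG1v21	CH2	T	16	254	Half-life increase
IGHG1	IGHG1v21	CH2	E	18	256	Half-life increase
IGHG1	IGHG1v22	CH2	Y	15.1	252	Half-life increase
IGHG1	IGHG1v22	CH2	T	16	254	Half-life increase
IGHG1	IGHG1v22	CH2	E	18	256	Half-life increase
IGHG1	IGHG1v22	CH3	K	113	433	Half-life increase
IGHG1	IGHG1v22	CH3	F	114	434	Half-life increase
IGHG1	IGHG1v22	CH3	H	116	436	Half-life increase
IGHG1	IGHG1v23	CH2	E	1.2	235	ADCC reduction;CDC reduction
IGHG1	IGHG1v24	CH3	L	107	428	Half-life increase
IGHG1	IGHG1v24	CH3	S	114	434	Half-life increase
IGHG1	IGHG1v25	CH2	E	29	267	B cell inhibition
IGHG1	IGHG1v25	CH2	F	113	328	B cell inhibition
IGHG1	IGHG1v26	CH3	Y	22	366	Knob in knobs-into-holes interaction
IGHG1	IGHG1v27	CH2	C	3	239	Site-specific drug attachment
IGHG1	IGHG1v28	CH2	insC3A	3	239	Site-specific drug attachment
IGHG1	IGHG1v29	CH2	A	84.4	297	No N-glycosylation site
IGHG1	IGHG1v30	CH2	G	84.4	297	No N-glycosylation site
IGHG1	IGHG1v31	CH3	T	86	407	Hole in knobs-into-holes interaction
IGHG1	IGHG1v32	CH3	W	22	366	Knob in knobs-into-holes interaction
IGHG1	IGHG1v33	CH3	S	22	366	Hole in knobs-into-holes interaction
IGHG1	IGHG1v33	CH3	A	24	368	Hole in knobs-into-holes interaction
IGHG1	IGHG1v33	CH3	V	86	407	Hole in knobs-into-holes interaction
IGHG1	IGHG1v34	CH3	G	109	430	Favors hexamerisation
IGHG1	IGHG1v35	CH2	E	29	267	CDC enhancement
IGHG1	IGHG1v36	CH2	Q	84.4	297	No N-glycosylation site
IGHG1	IGHG1v37	h	S	5	220	No disulfide bridge inter H-L
IGHG1	IGHG1v38	CH2	S	108	325	Abrogation of FcgRIII binding;Abrogation of C1q binding
IGHG1	IGHG1v38	CH2	F	113	328	Abrogation of FcgRIII binding;Abrogation of C1q binding
IGHG2	IGHG2v1	CH2	L	1.3	234	ADCC enhancement
IGHG2	IGHG2v1	CH2	L	1.2	235	ADCC enhancement
IGHG2	IGHG2v1	CH2	G	1.1	236	ADCC enhancement
IGHG2	IGHG2v1	CH2	G	1	237	ADCC enhancement
IGHG2	IGHG2v2	CH2	Q	30	268	ADCC reduction;CDC reduction
IGHG2	IGHG2v2	CH2	L	92	309	ADCC reduction;CDC reduction
IGHG2	IGHG2v2	CH2	S	115	330	ADCC reduction;CDC reduction
IGHG2	IGHG2v2	CH2	S	116	331	ADCC reduction;CDC reduction
IGHG2	IGHG2v3	CH2	A	1.2	235	ADCC reduction;CDC reduction
IGHG2	IGHG2v3	CH2	A	1	237	ADCC reduction;CDC reduction
IGHG2	IGHG2v3	CH2	S	2	238	ADCC reduction;CDC reduction
IGHG2	IGHG2v3	CH2	A	30	268	ADCC reduction;CDC reduction
IGHG2	IGHG2v3	CH2	L	92	309	ADCC reduction;CDC reduction
IGHG2	IGHG2v3	CH2	S	115	330	ADCC reduction;CDC reduction
IGHG2	IGHG2v3	CH2	S	116	331	ADCC reduction;CDC reduction
IGHG2	IGHG2v4	CH2	Q	14	250	Half-life increase
IGHG2	IGHG2v5	CH3	L	107	428	Half-life increase
IGHG2	IGHG2v6	CH2	Q	14	250	Half-life increase
IGHG2	IGHG2v6	CH3	L	107	428	Half-life increase
IGHG3	IGHG3v1	CH3	H	115	435	Half-life increase
IGHG4	IGHG4v1	CH2	L	1.3	234	ADCC enhancement
IGHG4	IGHG4v2	CH2	P	116	331	CDC enhancement
IGHG4	IGHG4v3	CH2	E	1.2	235	ADCC reduction;CDC reduction
IGHG4	IGHG4v4	CH2	A	1.3	234	ADCC reduction;CDC reduction
IGHG4	IGHG4v4	CH2	A	1.2	235	ADCC reduction;CDC reduction
IGHG4	IGHG4v5	h	P	10	228	Half-IG exchange reduction
IGHG4	IGHG4v6	CH3	K	88	409	Half-IG exchange reduction
IGHG4	IGHG4v21	CH2	Y	15.1	252	Half-life increase
IGHG4	IGHG4v21	CH2	T	16	254	Half-life increase
IGHG4	IGHG4v21	CH2	E	18	256	Half-life increase
IGHG4	IGHG4v36	CH2	Q	84.4	297	No N-glycosylation site
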