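# Allotype / isoallotype / lambda isotype marker rules.
# kind: allotype | isoallotype | isotype_marker
# required: semicolon-separated domain:position:AA conjunctions
#   (positions use dotted IMGT sub-position notation)
# corroborating: linked residues reported as evidence only, never required
marker	gene	kind	required	corroborating
G1m17	IGHG1	allotype	CH1:120:K
G1m3	IGHG1	allotype	CH1:103:I;CH1:120:R
nG1m17	IGHG1	isoallotype	CH1:120:R
G1m1	IGHG1	allotype	CH3:12:D;CH3:14:L
nG1m1	IGHG1	isoallotype	CH3:12:E;CH3:14:M
G1m27	IGHG1	allotype	CH3:101:I
G1m2	IGHG1	allotype	CH3:110:G
G1m28	IGHG1	allotype	CH3:115:R;CH3:116:Y
G2m23	IGHG2	allotype	CH2:45.1:M	CH1:92:T
G3m16	IGHG3	allotype	CH2:83:W
G3m21	IGHG3	allotype	CH2:82:L
nG3m21	IGHG3	isoallotype	CH2:82:P
G3m11	IGHG3	allotype	CH3:44:S
nG3m11	IGHG3	isoallotype	CH3:44:N
G3m10	IGHG3	allotype	CH3:44:S;CH3:101:I
G3m24	IGHG3	allotype	CH3:44:S;CH3:101:V
G3m27	IGHG3	allotype	CH3:101:I
G3m6	IGHG3	allotype	CH3:44:S;CH3:98:E
G3m13	IGHG3	allotype	CH3:44:S;CH3:98:Q
G3m26	IGHG3	allotype	CH3:115:R
G3m5	IGHG3	allotype	CH3:115:R;CH3:116:F
nG3m5	IGHG3	isoallotype	CH3:115:H;CH3:116:Y
G3m28	IGHG3	allotype	CH3:115:R;CH3:116:Y
G3m14	IGHG3	allotype	CH3:84:M;CH3:115:R;CH3:116:F
G3m15	IGHG3	allotype	CH3:39:M;CH3:115:H;CH3:116:Y
Mcg+	IGLC	isotype_marker	CL:1:N;CL:3:T
Mcg-	IGLC	isotype_marker	CL:1:A;CL:3:S
Ke+	IGLC	isotype_marker	CL:45:G
Ke-	IGLC	isotype_marker	CL:45:S
Oz+	IGLC	isotype_marker	CL:100:K
Oz-	IGLC	isotype_marker	CL:100:R
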