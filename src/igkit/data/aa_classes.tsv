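# IMGT-style amino acid classes, one row per standard residue.
# hydropathy: 3 classes; the hydrophobic class is the positive-hydropathy-index
# set {I, V, L, F, C, M, A}. volume: 5 classes. chem: 11 physicochemical classes.
# Memberships other than the hydrophobic set are package data and may be revised
# (see docs/methods.md).
residue	hydropathy	volume	chem
A	hydrophobic	very_small	aliphatic
C	hydrophobic	small	cysteine
D	hydrophilic	small	acidic
E	hydrophilic	medium	acidic
F	hydrophobic	very_large	aromatic
G	neutral	very_small	glycine
H	neutral	medium	histidine
I	hydrophobic	large	aliphatic
K	hydrophilic	large	basic
L	hydrophobic	large	aliphatic
M	hydrophobic	large	methionine
N	hydrophilic	small	amide
P	neutral	small	proline
Q	hydrophilic	medium	amide
R	hydrophilic	large	basic
S	neutral	very_small	hydroxyl
T	neutral	small	hydroxyl
V	hydrophobic	medium	aliphatic
W	neutral	very_large	aromatic
Y	neutral	very_large	aromatic
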