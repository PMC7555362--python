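# igkit

A toolkit for standardized immunoglobulin (antibody) sequence analysis:
IMGT unique numbering of V and C domains, CDR/FR delimitation, Collier de
Perles layouts, V-(D)-J junction decomposition, clonotype identification
with repertoire statistics, allotype / engineered-variant calling over the
constant regions, and a ground-truth rearrangement simulator.

## Who this is for

Immunogenetics and antibody-engineering work depends on a shared position
language: two antibodies can only be compared residue-by-residue once both
are numbered on the same scaffold.  `igkit` implements that scaffold — the
IMGT unique numbering — together with the analyses that are routinely
built on it: delimiting the hypervariable loops (CDR1/2/3-IMGT) and
framework regions, decrypting how a CDR3 was assembled from germline V, D
and J genes plus P/N nucleotides, grouping sequencing reads into
clonotypes, and reading serological markers (G1m, G2m, G3m, Km, Mcg/Ke/Oz)
or engineered Fc variants off the constant-domain residues.

## The numbering in one paragraph

A V domain folds into nine beta strands (A, B, C, C′, C″, D, E, F, G) and
three loops (BC, C′C″, FG).  Every residue receives a position from 1 to
128: CDR1-IMGT occupies 27–38, CDR2-IMGT 56–65, CDR3-IMGT 105–117.
Shorter segments leave *gaps* in a fixed order (for CDR3: 111, 112, 110,
113, …); longer CDR3 loops gain *additional positions* between 111 and
112 (112.1, 111.1, 112.2, 111.2, …), ordered 111 < 111.1 < … < 112.1 <
112.  Four hallmark residues anchor the fold: C23 (1st-CYS), W41
(CONSERVED-TRP), hydrophobic 89 and C104 (2nd-CYS); a V-DOMAIN adds
J-PHE/J-TRP 118 and the J-MOTIF F/W-G-X-G.  The JUNCTION spans positions
104–118 and is therefore always two residues longer than the CDR3.  C
domains use the same frame without the C′/C″ strands, with turns numbered
15.1–15.3, 45.1–45.9, 84.1–84.7/85.1–85.7 and 96.1–96.2.

## Worked example

Number the trastuzumab heavy-chain variable domain (120 aa) and delimit
its regions:

```python
from igkit.numbering import (V_TOPOLOGY, assign_numbering,
                             delimit_regions, verify_hallmarks)

vh = ("EVQLVESGGGLVQPGGSLRLSCAASGFNIKDTYIHWVRQAPGKGLEWVARIYPTNGYTRYADSVKG"
      "RFTISADTSKNTAYLQMNSLRAEDTAVYYCSRWGGDGFYAMDYWGQGTLVTVSS")
dom = assign_numbering(vh, (25, 8, 17, 8, 38, 13, 11), V_TOPOLOGY)
delim = delimit_regions(dom)
print("CDR lengths:", delim.cdr_notation)
print("FR lengths: ", delim.fr_notation)
print("JUNCTION length:", delim.junction_length)
print("hallmarks pass:", verify_hallmarks(dom)["all_pass"])
print(dom.gapped_sequence())
```

prints

```
CDR lengths: [8.8.13]
FR lengths:  [25.17.38.11]
JUNCTION length: 15
hallmarks pass: True
EVQLVESGG.GLVQPGGSLRLSCAASGFNI....KDTYIHWVRQAPGKGLEWVARIYPT..NGYTRYADSVK.GRFTISADTSKNTAYLQMNSLRAEDTAVYYCSRWGGDGFYAMDYWGQGTLVTVSS
```

`[8.8.13]` says the three CDR loops hold 8, 8 and 13 residues; the four
frameworks `[25.17.38.11]` sum to the canonical 91 of a VH.  The dots in
the gapped sequence mark the standardized gap positions (10, 31–34,
60–61, 73), which is what makes this domain alignable column-for-column
against any other numbered V domain.

Decompose a junction against germline references and print its
decryption string (germline lengths in parentheses, N regions in braces,
trimmed nucleotides negative, P nucleotides positive):

```python
from igkit.junction import decompose_junction, format_decryption

v3 = "tgcacgtc"                    # germline 3'V from codon 104, intact
j5 = "actactttgactactgg"          # germline 5'J through codon 118
dec = decompose_junction(v3 + "ga" + "aaat" + j5[2:], v3, [], j5)
print(format_decryption(dec))      # -> (8)+2{4}-2(15)
```

The `+2` is a P doublet (`ga`, the reverse complement of the intact V end
`tc`); the `-2` records two nucleotides trimmed from the J end.

A command-line surface wraps the same functions:

```bash
igkit --seed 4 simulate --out-prefix sim --n-clones 50
igkit clonotypes call --in sim.rearrangements.tsv --out clones.tsv
igkit repertoire --locus IGH
```

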