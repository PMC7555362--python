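# Methods

This note records the models, conventions and deliberate design choices
behind `igkit`, in the order a reader meets them.

## Position model

An IMGT position is a base integer 1–128 plus an optional sub-number
(`ImgtPosition`).  Comparison is structural, never lexical.  Two kinds of
sub-position exist:

* **Insertion blocks** around a loop apex, where the downstream half
  counts *toward* its base: 111 < 111.1 < … < 112.2 < 112.1 < 112.  The
  same scheme orders the C-domain DE turn (84.x ascending, 85.x
  descending into 85).
* **Turn additions** that simply ascend after their base: 15.1–15.3
  (AB), 45.1–45.9 (the transversal CD strand), 96.1–96.2 (EF).

`cdr3_position_sequence(n)` realizes the CDR3 length rules: at 13 the
full span 105–117; above 13 additional positions in the order 112.1,
111.1, 112.2, 111.2, …; below 13 gaps from the apex in the order 111,
112, 110, 113, 109, 114, ….  Both orders nest: the position set of any
length is contained in that of any longer length on the same side of 13.
This nesting is what the property tests assert for n = 1…40.

**CDR1/CDR2 gap order.** The removal order for short BC and C′C″ loops is
not spelled out alongside the CDR3 rule, so the package applies the same
apex-alternation scheme with apex pairs (32|33) and (60|61): 33, 32, 34,
31, … and 61, 60, 62, 59, ….  Two observations support this choice: a
BC loop of 8 then leaves gaps at 31–34 and a C′C″ loop of 8 leaves gaps
at 60–61, the classical patterns; and the C-domain BC loop (27–31,
34–38) equals the V scaffold minus exactly the first two removals.  The
order is data in the topology table and can be corrected without touching
code.

**Other gap rules.** FR1 of 25 gaps position 10; FR3 gaps 73, then 82,
then 81 (so 38 → {73}, 36 → {73, 81, 82}); FR4 of 10 gaps 128; the
C-domain A strand gaps 10 and D strand gaps 82; the C-domain G strand
shortens from 128 backwards.  Turn positions are additions, not
gap-leaving spans: an empty turn contributes no gap glyphs.

**DE-turn filling** is symmetric from both ends (84.1…84.⌈L/2⌉ then
85.⌊L/2⌋…85.1), documented as provisional since only the ranges
84.1–84.7/85.1–85.7 are fixed.

## Numbering transfer

`infer_boundaries` aligns a query to a numbered reference (Biopython
global alignment, match +5 / mismatch −4, gap open −12 / extend −2) and
reads region lengths off the aligned columns; insertions travel with the
region of the preceding aligned reference residue.  The alignment is a
means to transfer numbering, not a reported score, so the scoring scheme
is a convention, not a result.  A transfer that cannot place a cysteine
at 23 and 104 is refused (`LowConfidenceError`) rather than guessed.
Identity percentages count matches over positions occupied in *both*
domains; gap columns are excluded from the denominator.

## Amino acid classes

Three axes: hydropathy (3 classes), volume (5), chemical characteristics
(11).  Only the hydrophobic hydropathy set {I, V, L, F, C, M, A} is fixed
by definition; the remaining memberships ship as an editable fixture
(`data/aa_classes.tsv`) with a defensible default partition (volume by
side-chain size quintiles; 11 chemical classes separating G, P, C, M and
H as singleton chemistries).  A replacement's signature is the per-axis
equality triple, mapped to four similarity degrees (+++ very similar;
++−/+−+ similar; −−+/−+−/+−− dissimilar; −−− very dissimilar).
Non-standard residues (X, B, Z, \*) are rejected so change statistics
stay well defined.

## Collier de Perles

The layout is a pure function of the numbered domain: one glyph per
canonical position (occupied or hatched gap), anchors as squares, CDR
pearls coloured by loop with a palette variant for V-D-J vs V-J
products, hydrophobic residues (plus W) and prolines highlighted.  Pearls
sit on a per-strand serpentine grid; the contract covers strand
membership and ordering, not absolute geometry.  Two-layer form: V
domains put G, F, C, C′, C″ in front and A, B, E, D behind; C domains
G, F, C in front with the CD strand drawn transversally.  Hydrogen-bond
overlays are accepted as input data only — they derive from experimental
structures, which this package does not model.  The ">50% of analysed
sequences" hydrophobicity shading used online is population-derived;
here it is approximated by the fixed hydrophobic set, a deliberate
simplification.  SVG output is assembled as text with stable element
order, so identical layouts are byte-identical.

## Junction decomposition

The junction (codon 104 through codon 118) is explained as
(3′V) vP {N1} d5P (D) d3P {N2} jP (5′J).  The optimizer maximizes
germline-matched nucleotides (v+d+j), then total P length, with ties
broken toward longer D matches and lower gene-order index; at a fixed
(v, j) split only maximal-length D windows can win, which keeps the
search small.  P nucleotides (≤3 nt, reverse complement of the intact
coding end) are mutually exclusive with trimming at the same end, and
preferring P over N on ties reflects the germline-derived explanation
being the more parsimonious one.  A D call requires ≥5 matched
nucleotides (configurable); below that the decomposition is V-J-like
with a single N.  One D segment, no inversion.  The test suite checks
the optimizer's objective value against an independent
enumerate-every-decomposition oracle on hundreds of random junctions,
plus the reconstruction invariant on every output.

## Clonotypes and set comparison

An AA clonotype keys on (V gene, J gene, CDR3 amino acids, anchors C104
and W/F118); records failing anchor conservation are excluded with a
reason, never dropped silently.  V/J calls collapse to gene level by
default because allele assignment is frequently ambiguous in real data;
allele-level keying is a flag, and observed alleles are retained as
metadata.  Within each AA clonotype, nucleotide clonotypes split on the
CDR3 nucleotide sequence.  The representative member is the one with the
highest germline V identity (ties: longer sequence, then id).

Two repertoires are compared per gene by a pooled two-proportion z-test
with an unpooled 95% CI on the difference; p-values are adjusted by
seven procedures (Bonferroni, Holm, Šidák, Hochberg, Hommel,
Benjamini–Hochberg, Benjamini–Yekutieli), each toggleable.  A gene's
significance class records agreement: All_p (all procedures), Min_2p
(≥2), Only_BH, rawp (unadjusted only), non-significant.  The choice of
test statistic is a convention; the BH and Bonferroni decisions are
verified against their step-up / single-step definitions by brute force.

## Allotypes, Eu correspondence, engineered variants

Marker rules are conjunctions of residues at fixed C-domain positions,
shipped as an editable fixture: Km alleles from (45.1, 101) on IGKC;
G1m/nG1m from CH1 103/120 and CH3 12/14/101/110/115/116 on IGHG1 (the
allele table rows are matched whole); G2m23 determined by CH2 M45.1 with
the linked CH1 T92 reported as corroborating evidence only; the thirteen
G3m allotypes encoded as independent conjunctions over CH2 82/83 and the
two CH3 mosaics, all satisfied markers reported and conflicts surfaced
rather than resolved heuristically; Mcg/Ke/Oz as lambda isotype markers
with explicit negative states.  Isoallotypes live in a separate field
from allotypes.  Provisional alleles (expected from serology, not yet
sequenced) are flagged in the fixture.

The Eu↔IMGT position table is derived from the engineered-variant
catalog (every printed pair) and validated for per-domain bijectivity at
load; chain-numbering positions quoted in antibody descriptions are
excluded because they are not Eu numbers.  Variant naming is an
exact-change-set match against the catalog relative to allele \*01;
unmatched sets get a deterministic `vNEW-<sha256 prefix>` label plus the
nearest catalogued variant by change overlap.

## Locus tables

Two fixtures back the repertoire module: a per-group census (major locus
vs orphons, genes and alleles) and gene-level tables of the potential
repertoire (subgroup, CDR lengths, allele counts by functionality, CNV
and cluster tags, gene order).  The two are deliberately separate: the
census counts every gene including pseudogenes unassigned to subgroups,
while the gene tables list only subgroups carrying at least one
functional allele, so the census cannot be recomputed from the gene rows.
Cluster sizes (e.g. the 40-gene IGK proximal cluster) and the IGHM
membrane-anchor exon model (M1 = 39 aa, M2 = 2 aa; CO 13 + TM 27 + CY 1
= 41) are locus facts stored alongside.  Haplotype ranges ("38 to 46
functional IGHV") are stored as min/max bounds, never a single number.
The combinatorial product multiplies functional V × D × J (V × J for
light chains) gene counts and applies no junctional factor.

## Simulator

The simulator defines the study conditions for end-to-end tests.  Toy
germline sets satisfy the hallmark constraints by construction.
Rearrangement follows D-J then V-DJ joining; 12/23 recombination-signal
geometry is honored structurally (only V–D and D–J pairings occur), not
sequence-simulated.  Defaults, chosen once as realistic desk-scale
conditions since no quantitative distributions are fixed by the
standard: geometric trims with mean 2 per coding end (capped so codons
104/118 stay intact), P probability 0.5 at untrimmed ends with length
uniform on 1–3, Poisson N lengths with mean 4 and P(g) = 0.4 (the 'g'
preference of terminal transferase), SHM off unless requested.  SHM is
per-site Bernoulli with hotspot positions — motifs (a/t)a, t(a/t),
(a/g)g(c/t)(a/t), (a/t)(a/g)c(c/t) — upweighted by a ×5 multiplier and
transitions favored 2:1 over transversions; this is a modeling choice,
not a calibrated rate.  The junction is padded to a codon multiple so
every record translates cleanly, and clones are drawn until their
(V, J, CDR3) keys are distinct so the planted partition is recoverable
in principle.

Each record carries full ground truth plus a `nondegenerate` flag
computed by direct string checks (planted germline matches maximal and
non-extendable, no spurious P, planted D window the unique best match):
on flagged records the decomposition must equal the truth *exactly*,
which is the strongest statement random sequences allow — a draw whose N
nucleotides happen to extend a germline match has genuinely ambiguous
provenance, and no analysis could recover the plant.

What the simulator does *not* emulate: somatic insertion/deletion,
allele-level germline variation, sequencing error, class switching,
multiple or inverted D segments.  Passing end-to-end tests therefore
demonstrates correctness of the decomposition and grouping logic under
clean inputs, not robustness to real sequencing artefacts.

## Problem sizes

The test suite runs the simulator at 30–200 clones (up to ~1,000
records), checks the junction optimizer against the brute-force oracle
on 500 random junctions of ≤45 nt, and evaluates stochastic assertions
(g-bias composition, hotspot enrichment) at 10,000+ sites against exact
binomial / log-ratio 99% bounds with fixed seeds.  These sizes keep the
whole suite under a minute while leaving the stochastic tests enough
power that a wrong bias or a missing enrichment fails deterministically.

## Known limitations

* The CDR1/CDR2 apex removal order and the DE-turn filling are
  documented conventions pending an authoritative table; both are data.
* The 11-class chemical partition is a package default, not a standard.
* `infer_boundaries` assumes a complete domain (length 70–150) and a
  fully numbered reference; fragments and scFv constructs are out of
  scope.
* Junction decomposition does not tolerate somatic mutation inside the
  junction; mutated junctions decompose to the nearest germline
  explanation.
* Eu correspondence covers exactly the catalogued constant-domain
  positions; it is a lookup, not a general alignment between numbering
  systems.
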