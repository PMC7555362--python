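"""IMGT unique numbering for V and C domains.

The IMGT unique numbering assigns every residue of an immunoglobulin (or TR)
domain a standardized position from 1 to 128, independent of the actual
sequence length.  A V domain folds into nine antiparallel beta strands
(A, B, C, C', C'', D, E, F, G) and three loops (BC, C'C'', FG); in a
V-DOMAIN the loops are the CDR1/CDR2/CDR3-IMGT and the strands form the
FR1..FR4-IMGT.  A C domain has seven strands, a transversal CD strand,
two loops and three additional turns (AB, DE, EF) numbered with
sub-positions (15.1-15.3, 84.1-84.7/85.1-85.7, 96.1-96.2).

Shorter-than-maximal segments leave standardized *gaps* (unoccupied
positions); longer-than-maximal CDR3 loops receive *additional positions*
between 111 and 112 (111.1, 112.1, ...).  Both follow fixed orders so that
two domains of different lengths remain position-by-position comparable.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field

from Bio import Align

from .aa_properties import HYDROPHOBIC_SET

__all__ = [
    "ImgtPosition",
    "DomainTopology",
    "NumberedDomain",
    "NumberedResidue",
    "RegionDelimitation",
    "TopologyError",
    "LowConfidenceError",
    "V_TOPOLOGY",
    "C_TOPOLOGY",
    "cdr3_position_sequence",
    "loop_position_sequence",
    "assign_numbering",
    "infer_boundaries",
    "delimit_regions",
    "verify_hallmarks",
    "region_identity",
]


class TopologyError(ValueError):
    """A segment length is incompatible with the domain topology."""


class LowConfidenceError(ValueError):
    """Numbering transfer failed (hallmark anchors could not be aligned)."""


# Bases whose sub-positions grow *toward* the base (112.2 < 112.1 < 112),
# i.e. the downstream half of a symmetric insertion block.
_DESCENDING_SUB_BASES = frozenset({112, 85})


@functools.total_ordering
@dataclass(frozen=True)
class ImgtPosition:
    """One IMGT position: an integer base 1-128 plus an optional sub-number.

    Sub-positions occur in the CDR3 insertion block (111.1 ... 112.1) and in
    the C-domain turns (15.x, 45.x, 84.x, 85.x, 96.x).  Comparison is
    structural, never lexical: within the 111/112 (and 84/85) block the
    order is 111 < 111.1 < ... < 112.2 < 112.1 < 112.
    """

    base: int
    sub: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.base <= 128:
            raise ValueError(f"base position {self.base} outside 1-128")
        if self.sub is not None and self.sub < 1:
            raise ValueError(f"sub-position must be positive, got {self.sub}")

    @property
    def sort_key(self) -> tuple[int, int, int]:
        if self.sub is None:
            return (self.base, 1 if self.base in _DESCENDING_SUB_BASES else 0, 0)
        if self.base in _DESCENDING_SUB_BASES:
            return (self.base, 0, -self.sub)
        return (self.base, 1, self.sub)

    def __lt__(self, other: "ImgtPosition") -> bool:
        return self.sort_key < other.sort_key

    def __str__(self) -> str:
        return str(self.base) if self.sub is None else f"{self.base}.{self.sub}"

    @classmethod
    def parse(cls, text: str) -> "ImgtPosition":
        m = re.fullmatch(r"(\d+)(?:\.(\d+))?", text.strip())
        if not m:
            raise ValueError(f"not an IMGT position: {text!r}")
        return cls(int(m.group(1)), int(m.group(2)) if m.group(2) else None)


def _p(base: int, sub: int | None = None) -> ImgtPosition:
    return ImgtPosition(base, sub)


# --------------------------------------------------------------------------
# position sequences for variable-length segments


def cdr3_position_sequence(length: int) -> list[ImgtPosition]:
    """IMGT positions of a CDR3 (FG loop) of the given length.

    Length 13 is the canonical full span 105-117.  Longer loops gain
    additional positions between 111 and 112 in the order
    112.1, 111.1, 112.2, 111.2, ...; shorter loops lose positions from the
    loop apex in the order 111, 112, 110, 113, 109, 114, ...
    """
    if length < 1:
        raise TopologyError(f"CDR3 length must be >= 1, got {length}")
    base = [_p(i) for i in range(105, 118)]
    if length == 13:
        return base
    if length > 13:
        extra = []
        for k in range(length - 13):
            i = k // 2 + 1
            extra.append(_p(112, i) if k % 2 == 0 else _p(111, i))
        return sorted(base + extra)
    removal = _apex_removal_order(list(range(105, 118)), lower_apex_index=6)
    drop = set(removal[: 13 - length])
    return [p for p in base if p.base not in drop]


def _apex_removal_order(bases: list[int], lower_apex_index: int) -> list[int]:
    """Alternating removal order starting at the loop apex.

    For the FG loop (105..117) the apex pair is (111|112) and the order is
    111, 112, 110, 113, 109, 114, ...  (lower apex first, then alternate
    outward).
    """
    lo, hi = lower_apex_index, lower_apex_index + 1
    order = []
    while lo >= 0 or hi < len(bases):
        if lo >= 0:
            order.append(bases[lo])
            lo -= 1
        if hi < len(bases):
            order.append(bases[hi])
            hi += 1
    return order


# CDR1 (BC loop) and CDR2 (C'C'' loop) removal orders: same apex-alternation
# scheme with apex pairs (32|33) and (60|61), upper apex removed first.
# These orders are data, isolated here so they can be corrected without code
# change elsewhere.
_BC_SCAFFOLD = list(range(27, 39))          # 27..38, max 12
_BC_REMOVAL = [33, 32, 34, 31, 35, 30, 36, 29, 37, 28, 38, 27]
_CPP_SCAFFOLD = list(range(56, 66))         # 56..65, max 10
_CPP_REMOVAL = [61, 60, 62, 59, 63, 58, 64, 57, 65, 56]
# C-domain BC loop: positions 32 and 33 are absent by definition (first two
# removals), leaving 27-31 and 34-38, max 10.
_C_BC_SCAFFOLD = [b for b in _BC_SCAFFOLD if b not in (32, 33)]
_C_BC_REMOVAL = _BC_REMOVAL[2:]


def loop_position_sequence(loop: str, length: int) -> list[ImgtPosition]:
    """Positions of a BC (CDR1) or C'C'' (CDR2) loop of the given length."""
    scaffolds = {
        "BC": (_BC_SCAFFOLD, _BC_REMOVAL),
        "C'C''": (_CPP_SCAFFOLD, _CPP_REMOVAL),
    }
    if loop not in scaffolds:
        raise ValueError(f"unknown loop {loop!r}; expected 'BC' or \"C'C''\"")
    scaffold, removal = scaffolds[loop]
    return _gapped(scaffold, removal, length, loop)


def _gapped(scaffold: list[int], removal: list[int], length: int, label: str
            ) -> list[ImgtPosition]:
    if length < 0 or length > len(scaffold):
        raise TopologyError(
            f"{label} length {length} outside 0-{len(scaffold)}")
    drop = set(removal[: len(scaffold) - length])
    return [_p(b) for b in scaffold if b not in drop]


def _turn_positions(base: int, max_sub: int, length: int, label: str
                    ) -> list[ImgtPosition]:
    if length < 0 or length > max_sub:
        raise TopologyError(f"{label} length {length} outside 0-{max_sub}")
    return [_p(base, i) for i in range(1, length + 1)]


def _de_turn_positions(length: int) -> list[ImgtPosition]:
    # 84.1..84.7 then 85.7..85.1: fill symmetrically from both ends,
    # the 84.x half ascending, the 85.x half descending toward 85.
    if length < 0 or length > 14:
        raise TopologyError(f"DE-TURN length {length} outside 0-14")
    k = (length + 1) // 2
    m = length // 2
    return [_p(84, i) for i in range(1, k + 1)] + \
           [_p(85, i) for i in range(m, 0, -1)]


# --------------------------------------------------------------------------
# topologies


@dataclass(frozen=True)
class Segment:
    """One topology segment: a strand, turn or loop with its gap rule."""

    label: str            # strand/turn/loop name (A, BC, CD, ...)
    region: str           # FR1/CDR1/... for V; the segment label for C
    lengths: tuple        # admissible lengths (or range for variable ones)
    positions: object     # callable length -> list[ImgtPosition]


def _fixed(bases: list[int]):
    def gen(length: int, _bases=tuple(bases)) -> list[ImgtPosition]:
        if length != len(_bases):
            raise TopologyError(
                f"segment spanning {_bases[0]}-{_bases[-1]} requires length "
                f"{len(_bases)}, got {length}")
        return [_p(b) for b in _bases]
    return gen


def _gap_at(bases: list[int], gap_order: list[int], min_len: int):
    def gen(length: int) -> list[ImgtPosition]:
        full = len(bases)
        if not min_len <= length <= full:
            raise TopologyError(
                f"segment spanning {bases[0]}-{bases[-1]} admits lengths "
                f"{min_len}-{full}, got {length}")
        drop = set(gap_order[: full - length])
        return [_p(b) for b in bases if b not in drop]
    return gen


@dataclass(frozen=True)
class DomainTopology:
    """Segment layout, anchors and conserved hallmarks of a domain kind."""

    domain_kind: str                 # "V" or "C"
    segments: tuple
    anchors: frozenset
    conserved: dict = field(default_factory=dict)

    @property
    def segment_labels(self) -> list[str]:
        return [s.label for s in self.segments]

    _C_SUB_SEGMENTS = {15: "AB", 45: "CD", 84: "DE", 85: "DE", 96: "EF"}

    def strand_of(self, position: ImgtPosition) -> str:
        if (self.domain_kind == "C" and position.sub is not None
                and position.base in self._C_SUB_SEGMENTS):
            return self._C_SUB_SEGMENTS[position.base]
        for label, lo, hi in self._strand_spans():
            if lo <= position.base <= hi:
                return label
        raise ValueError(f"position {position} outside domain span")

    def _strand_spans(self):
        if self.domain_kind == "V":
            return [("A", 1, 15), ("B", 16, 26), ("BC", 27, 38), ("C", 39, 46),
                    ("C'", 47, 55), ("C'C''", 56, 65), ("C''", 66, 74),
                    ("D", 75, 84), ("E", 85, 96), ("F", 97, 104),
                    ("FG", 105, 117), ("G", 118, 128)]
        return [("A", 1, 15), ("B", 16, 26), ("BC", 27, 38), ("C", 39, 45),
                ("CD", 46, 76), ("D", 77, 84), ("E", 85, 96), ("F", 97, 104),
                ("FG", 105, 117), ("G", 118, 128)]


def _v_fr3(length: int) -> list[ImgtPosition]:
    # C''(66-74) + D(75-84) + E(85-96) + F(97-104): 39 positions max;
    # gaps in order 73 (C''), then 82, 81 (D-strand).
    return _gap_at(list(range(66, 105)), [73, 82, 81], 36)(length)


V_TOPOLOGY = DomainTopology(
    domain_kind="V",
    segments=(
        Segment("FR1", "FR1", (25, 26), _gap_at(list(range(1, 27)), [10], 25)),
        Segment("CDR1", "CDR1", (0, 12),
                lambda n: loop_position_sequence("BC", n)),
        Segment("FR2", "FR2", (17,), _fixed(list(range(39, 56)))),
        Segment("CDR2", "CDR2", (0, 10),
                lambda n: loop_position_sequence("C'C''", n)),
        Segment("FR3", "FR3", (36, 39), _v_fr3),
        Segment("CDR3", "CDR3", (1, 40), cdr3_position_sequence),
        Segment("FR4", "FR4", (10, 11),
                _gap_at(list(range(118, 129)), [128], 10)),
    ),
    anchors=frozenset({26, 39, 55, 66, 104, 118}),
    conserved={23: "1st-CYS", 41: "CONSERVED-TRP", 89: "hydrophobic",
               104: "2nd-CYS", 118: "J-PHE/J-TRP"},
)

C_TOPOLOGY = DomainTopology(
    domain_kind="C",
    segments=(
        Segment("A", "A", (14, 15), _gap_at(list(range(1, 16)), [10], 14)),
        Segment("AB", "AB", (0, 3),
                lambda n: _turn_positions(15, 3, n, "AB-TURN")),
        Segment("B", "B", (11,), _fixed(list(range(16, 27)))),
        Segment("BC", "BC", (0, 10),
                lambda n: _gapped(_C_BC_SCAFFOLD, _C_BC_REMOVAL, n, "BC")),
        Segment("C", "C", (7,), _fixed(list(range(39, 46)))),
        Segment("CD", "CD", (0, 9),
                lambda n: _turn_positions(45, 9, n, "CD-STRAND")),
        Segment("D", "D", (7, 8), _gap_at(list(range(77, 85)), [82], 7)),
        Segment("DE", "DE", (0, 14), _de_turn_positions),
        Segment("E", "E", (12,), _fixed(list(range(85, 97)))),
        Segment("EF", "EF", (0, 2),
                lambda n: _turn_positions(96, 2, n, "EF-TURN")),
        Segment("F", "F", (8,), _fixed(list(range(97, 105)))),
        Segment("FG", "FG", (1, 13), cdr3_position_sequence),
        Segment("G", "G", (1, 11),
                _gap_at(list(range(118, 129)),
                        list(range(128, 117, -1)), 1)),
    ),
    anchors=frozenset({26, 39, 45, 77, 104, 118}),
    conserved={23: "1st-CYS", 41: "CONSERVED-TRP", 89: "hydrophobic",
               104: "2nd-CYS"},
)


# --------------------------------------------------------------------------
# numbered domains


@dataclass(frozen=True)
class NumberedResidue:
    position: ImgtPosition
    aa: str
    region: str
    segment: str
    anchor: bool = False
    conserved: str | None = None


@dataclass(frozen=True)
class NumberedDomain:
    """A domain sequence with every residue bound to an IMGT position."""

    domain_kind: str
    residues: tuple
    boundaries: tuple          # per-segment lengths used for the numbering
    gaps: frozenset = frozenset()

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def positions(self) -> list[ImgtPosition]:
        return [r.position for r in self.residues]

    def residue_at(self, position: ImgtPosition) -> NumberedResidue | None:
        for r in self.residues:
            if r.position == position:
                return r
        return None

    def aa_at(self, position: ImgtPosition) -> str | None:
        r = self.residue_at(position)
        return r.aa if r else None

    def region_lengths(self) -> dict:
        out: dict = {}
        for r in self.residues:
            out[r.region] = out.get(r.region, 0) + 1
        return out

    def gapped_sequence(self) -> str:
        """Sequence over the canonical span with '.' at unoccupied positions."""
        occupied = {r.position: r.aa for r in self.residues}
        span = sorted(set(occupied) | set(self.gaps))
        return "".join(occupied.get(p, ".") for p in span)

    def to_records(self) -> list[dict]:
        return [
            {
                "position": str(r.position),
                "aa": r.aa,
                "region": r.region,
                "segment": r.segment,
                "anchor": r.anchor,
                "conserved": r.conserved or "",
            }
            for r in self.residues
        ]


@dataclass(frozen=True)
class RegionDelimitation:
    """CDR/FR length notation of a delimited V-DOMAIN."""

    cdr_lengths: tuple
    fr_lengths: tuple

    @property
    def junction_length(self) -> int:
        # JUNCTION = CDR3 plus the two anchors 104 and 118.
        return self.cdr_lengths[2] + 2

    @property
    def cdr_notation(self) -> str:
        return "[" + ".".join(map(str, self.cdr_lengths)) + "]"

    @property
    def fr_notation(self) -> str:
        return "[" + ".".join(map(str, self.fr_lengths)) + "]"


def _topology_for(kind: str) -> DomainTopology:
    kinds = {"V": V_TOPOLOGY, "C": C_TOPOLOGY}
    if kind not in kinds:
        raise ValueError(f"unknown domain kind {kind!r}")
    return kinds[kind]


def assign_numbering(sequence: str, boundaries, topology: DomainTopology
                     ) -> NumberedDomain:
    """Bind each residue of ``sequence`` to an IMGT position.

    ``boundaries`` gives one length per topology segment (7 values for a V
    domain: FR1, CDR1, FR2, CDR2, FR3, CDR3, FR4; 13 for a C domain).
    """
    boundaries = tuple(int(b) for b in boundaries)
    if len(boundaries) != len(topology.segments):
        raise TopologyError(
            f"{topology.domain_kind} domain requires "
            f"{len(topology.segments)} segment lengths, got {len(boundaries)}")
    if sum(boundaries) != len(sequence):
        raise TopologyError(
            f"segment lengths sum to {sum(boundaries)} but sequence has "
            f"{len(sequence)} residues")
    residues = []
    occupied = set()
    cursor = 0
    for seg, seg_len in zip(topology.segments, boundaries):
        positions = seg.positions(seg_len)
        for pos in positions:
            aa = sequence[cursor].upper()
            residues.append(NumberedResidue(
                position=pos,
                aa=aa,
                region=seg.region,
                segment=topology.strand_of(pos),
                anchor=pos.sub is None and pos.base in topology.anchors,
                conserved=topology.conserved.get(pos.base)
                if pos.sub is None else None,
            ))
            occupied.add(pos)
            cursor += 1
    canonical = _canonical_span(topology, boundaries)
    gaps = frozenset(canonical - occupied)
    residues.sort(key=lambda r: r.position.sort_key)
    for a, b in zip(residues, residues[1:]):
        if not a.position < b.position:
            raise TopologyError(
                f"duplicate or unordered positions {a.position}, {b.position}")
    return NumberedDomain(
        domain_kind=topology.domain_kind,
        residues=tuple(residues),
        boundaries=boundaries,
        gaps=gaps,
    )


def _canonical_span(topology: DomainTopology, boundaries) -> set:
    """All positions of the canonical scaffold for the given boundaries.

    Turn sub-positions exist only when occupied (they are additions, not
    gap-leaving spans); the FG loop is canonical at 13, with additional
    positions beyond 13 occupied by definition.
    """
    span = set()
    for seg, seg_len in zip(topology.segments, boundaries):
        if seg.label in ("AB", "CD", "DE", "EF"):
            full = seg_len
        elif seg.region == "CDR3" or seg.label == "FG":
            full = max(seg_len, 13)
        else:
            full = max(seg.lengths)
        span.update(seg.positions(full))
    return span


def delimit_regions(domain: NumberedDomain) -> RegionDelimitation:
    """CDR-IMGT and FR-IMGT lengths of a numbered V-DOMAIN."""
    if domain.domain_kind != "V":
        raise ValueError("region delimitation is defined for V domains only")
    lengths = domain.region_lengths()
    return RegionDelimitation(
        cdr_lengths=tuple(lengths.get(r, 0) for r in ("CDR1", "CDR2", "CDR3")),
        fr_lengths=tuple(lengths.get(r, 0)
                         for r in ("FR1", "FR2", "FR3", "FR4")),
    )


# --------------------------------------------------------------------------
# hallmarks


_J_MOTIF_BASES = (118, 119, 120, 121)


def verify_hallmarks(domain: NumberedDomain) -> dict:
    """Check the conserved hallmark residues of a numbered domain.

    Positions 23 (1st-CYS), 41 (CONSERVED-TRP), 89 (hydrophobic) and
    104 (2nd-CYS) are common to V and C domains; a V-DOMAIN additionally
    carries J-PHE/J-TRP 118 and the J-MOTIF F/W-G-X-G at 118-121.
    Deviations are reported, not fatal.
    """
    checks: dict = {}
    expectations = [
        (23, lambda aa: aa == "C", "C"),
        (41, lambda aa: aa == "W", "W"),
        (89, lambda aa: aa in HYDROPHOBIC_SET, "hydrophobic"),
        (104, lambda aa: aa == "C", "C"),
    ]
    if domain.domain_kind == "V":
        expectations.append((118, lambda aa: aa in "FW", "F/W"))
    for base, ok, expected in expectations:
        aa = domain.aa_at(_p(base))
        checks[base] = {
            "expected": expected,
            "observed": aa,
            "status": "pass" if aa is not None and ok(aa)
            else ("missing" if aa is None else "deviation"),
        }
    if domain.domain_kind == "V":
        motif = [domain.aa_at(_p(b)) for b in _J_MOTIF_BASES]
        motif_ok = (None not in motif and motif[0] in "FW"
                    and motif[1] == "G" and motif[3] == "G")
        checks["J-MOTIF"] = {
            "expected": "F/W-G-X-G",
            "observed": "".join(aa or "-" for aa in motif),
            "status": "pass" if motif_ok else "deviation",
        }
    checks["all_pass"] = all(
        v["status"] == "pass" for k, v in checks.items() if k != "all_pass")
    return checks


# --------------------------------------------------------------------------
# numbering transfer by alignment


_V_REGION_NAMES = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -2
    return aligner


def infer_boundaries(sequence: str, reference: NumberedDomain
                     ) -> tuple[tuple, dict]:
    """Transfer the reference numbering onto a query sequence by alignment.

    The query is globally aligned to the reference's (ungapped) sequence;
    per-segment lengths are read off the aligned columns, with query
    insertions attributed to the segment of the preceding aligned reference
    residue.  Raises :class:`LowConfidenceError` when no cysteine aligns to
    position 23 or 104.
    """
    sequence = sequence.upper()
    if not 70 <= len(sequence) <= 150:
        raise LowConfidenceError(
            f"sequence length {len(sequence)} implausible for a domain")
    topology = _topology_for(reference.domain_kind)
    ref_seq = reference.sequence
    alignment = _make_aligner().align(ref_seq, sequence)[0]
    # map: query index -> reference residue index (or None for insertions)
    region_names = ([s.region for s in topology.segments])
    ref_region = [r.region for r in reference.residues]
    counts = {name: 0 for name in region_names}
    aligned_to: dict = {}
    current_region = region_names[0]
    ref_cols, query_cols = alignment.aligned
    pairs = []
    for (rs, re_), (qs, qe) in zip(ref_cols, query_cols):
        for i in range(re_ - rs):
            pairs.append((rs + i, qs + i))
    matched_q = {q: r for r, q in pairs}
    for q in range(len(sequence)):
        if q in matched_q:
            current_region = ref_region[matched_q[q]]
        counts[current_region] += 1
        aligned_to[q] = matched_q.get(q)
    # hallmark anchors: a cysteine must sit at 23 and 104
    for base in (23, 104):
        ref_idx = next(
            (i for i, r in enumerate(reference.residues)
             if r.position == _p(base)), None)
        q_idx = next((q for q, r in matched_q.items() if r == ref_idx), None)
        if q_idx is None or sequence[q_idx] != "C":
            raise LowConfidenceError(
                f"no cysteine alignable to position {base}")
    boundaries = tuple(counts[name] for name in region_names)
    numbered = assign_numbering(sequence, boundaries, topology)
    report = {
        "boundaries": boundaries,
        "identity": {
            name: region_identity(numbered, reference, name)
            for name in region_names if counts[name] > 0
            and any(r.region == name for r in reference.residues)
        },
    }
    return boundaries, report


def region_identity(query: NumberedDomain, reference: NumberedDomain,
                    region: str) -> float:
    """Percent identity over shared occupied positions of one region.

    Positions that are gaps in either domain are excluded from the
    denominator.  ``region`` may also be ``"V-REGION"`` (everything up to
    and including position 104) or ``"all"``.
    """
    if query.domain_kind != reference.domain_kind:
        raise ValueError("domains numbered on different topologies")

    def in_scope(r: NumberedResidue) -> bool:
        if region == "all":
            return True
        if region == "V-REGION":
            return r.position.sort_key <= _p(104).sort_key
        return r.region == region

    q_map = {r.position: r.aa for r in query.residues if in_scope(r)}
    ref_map = {r.position: r.aa for r in reference.residues if in_scope(r)}
    shared = set(q_map) & set(ref_map)
    if not shared:
        raise ValueError(f"region {region!r} empty in query or reference")
    matches = sum(1 for p in shared if q_map[p] == ref_map[p])
    return round(100.0 * matches / len(shared), 1)
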