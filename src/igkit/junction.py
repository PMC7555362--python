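"""V-(D)-J junction decomposition.

The JUNCTION is the nucleotide stretch from codon 104 (2nd-CYS) to codon
118 (J-PHE/J-TRP).  During V-(D)-J rearrangement an exonuclease trims the
coding ends (3'V, both D ends, 5'J); untrimmed ends may instead carry P
nucleotides -- short (1-3 nt) palindromes of the intact coding end arising
from asymmetric hairpin opening -- and the terminal transferase inserts
template-independent N nucleotides between the segments.

:func:`decompose_junction` explains an observed junction against germline
references as::

    (3'V) vP {N1} d5P (D) d3P {N2} jP (5'J)

maximizing germline-matched nucleotides (then P length).  Trimming and P
are mutually exclusive at each coding end, and the concatenation of the
parts reconstructs the junction exactly.

The compact "decryption" string puts germline lengths in parentheses,
N lengths in braces, and signed integers at the coding ends: negative for
trimmed nucleotides, positive for P nucleotides.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "JunctionDecomposition",
    "JunctionError",
    "decompose_junction",
    "format_decryption",
    "parse_decryption",
]

_COMPLEMENT = str.maketrans("acgtACGT", "tgcaTGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class JunctionError(ValueError):
    """Invalid junction input or malformed decryption string."""


@dataclass(frozen=True)
class JunctionDecomposition:
    """Partition of a junction into germline matches, P and N segments."""

    v_len: int
    j_len: int
    d_len: int = 0
    d_call: str | None = None
    v_trim: int = 0
    d5_trim: int = 0
    d3_trim: int = 0
    j_trim: int = 0
    v_p: str = ""
    d5_p: str = ""
    d3_p: str = ""
    j_p: str = ""
    n1: str = ""
    n2: str = ""
    v_match: str = ""
    d_match: str = ""
    j_match: str = ""

    def __post_init__(self) -> None:
        for trim, p, end in [
            (self.v_trim, self.v_p, "3'V"),
            (self.d5_trim, self.d5_p, "5'D"),
            (self.d3_trim, self.d3_p, "3'D"),
            (self.j_trim, self.j_p, "5'J"),
        ]:
            if trim > 0 and p:
                raise JunctionError(
                    f"trim and P nucleotides are mutually exclusive at {end}")
            if len(p) > 3:
                raise JunctionError(f"P length at {end} exceeds 3 nt")

    @property
    def has_d(self) -> bool:
        return self.d_call is not None

    def reconstruct(self) -> str:
        """Concatenate the parts back into the junction sequence."""
        return (self.v_match + self.v_p + self.n1 + self.d5_p + self.d_match
                + self.d3_p + self.n2 + self.j_p + self.j_match)

    @property
    def matched_total(self) -> int:
        return self.v_len + self.d_len + self.j_len


def _longest_common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _p_extension(available: str, intact_end_rc: str) -> int:
    """Longest P run (<=3) at the start of ``available`` matching the
    reverse complement of the intact coding end."""
    best = 0
    for p in range(1, min(3, len(available), len(intact_end_rc)) + 1):
        if available[:p] == intact_end_rc[:p]:
            best = p
        else:
            break
    return best


def decompose_junction(junction_nt: str, v3_ref: str, d_refs,
                       j5_ref: str, min_d_length: int = 5
                       ) -> JunctionDecomposition:
    """Best decomposition of ``junction_nt`` against germline references.

    ``v3_ref`` is the germline V from codon 104 through its 3' end;
    ``j5_ref`` the germline J from its 5' end through codon 118; ``d_refs``
    an ordered mapping/list of (name, sequence) in locus gene order.  All
    sequences are 5'->3'.

    The search maximizes germline-matched nucleotides (v + d + j), then
    total P length, with ties broken toward longer D matches and lower D
    gene-order index.  A D segment is called only when its match reaches
    ``min_d_length``; otherwise the decomposition is V-J-like with a
    single N region (stored as ``n1``).
    """
    jx = junction_nt.lower()
    v3 = v3_ref.lower()
    j5 = j5_ref.lower()
    if len(jx) < 6:
        raise JunctionError(f"junction of {len(jx)} nt is too short")
    if d_refs is None:
        d_refs = []
    d_items = list(d_refs.items()) if hasattr(d_refs, "items") else list(d_refs)
    d_items = [(name, seq.lower()) for name, seq in d_items]

    L = len(jx)
    max_v = _longest_common_prefix(jx, v3)
    max_j = _longest_common_prefix(jx[::-1], j5[::-1])

    best = None
    best_key = None
    for v_len in range(max_v, -1, -1):
        for j_len in range(max_j, -1, -1):
            if v_len + j_len > L:
                continue
            middle = jx[v_len:L - j_len]
            for cand in _d_candidates(middle, d_items, min_d_length):
                dec = _build(jx, v3, j5, v_len, j_len, cand)
                key = (dec.matched_total,
                       len(dec.v_p) + len(dec.d5_p) + len(dec.d3_p)
                       + len(dec.j_p),
                       dec.d_len,
                       -(cand[3] if cand else 0),
                       dec.v_len, dec.j_len)
                if best_key is None or key > best_key:
                    best, best_key = dec, key
    assert best is not None
    return best


def _d_candidates(middle: str, d_items, min_d_length):
    """Yield D placements (name, offset, window, gene_index, d5_trim, d3_trim)
    plus the no-D option."""
    yield None
    for idx, (name, d_seq) in enumerate(d_items):
        if not d_seq:
            continue
        # only maximal-length matches can win for this gene at a fixed
        # (v_len, j_len): matched total dominates every later tie-break
        for wlen in range(min(len(d_seq), len(middle)), min_d_length - 1, -1):
            found = False
            for start in range(len(d_seq) - wlen + 1):
                window = d_seq[start:start + wlen]
                off = middle.find(window)
                while off != -1:
                    found = True
                    yield (name, off, window, idx, start,
                           len(d_seq) - (start + wlen), d_seq)
                    off = middle.find(window, off + 1)
            if found:
                break


def _build(jx, v3, j5, v_len, j_len, cand) -> JunctionDecomposition:
    L = len(jx)
    v_trim = len(v3) - v_len
    j_trim = len(j5) - j_len
    middle_start = v_len
    middle_end = L - j_len
    # P at the 3'V end (only when untrimmed)
    v_p = ""
    if v_trim == 0 and v_len > 0:
        limit = middle_end if cand is None else middle_start + cand[1]
        avail = jx[middle_start:limit]
        p = _p_extension(avail, revcomp(v3))
        v_p = avail[:p]
    # P at the 5'J end
    j_p = ""
    if j_trim == 0 and j_len > 0:
        lo = middle_start + len(v_p)
        if cand is not None:
            lo = max(lo, middle_start + cand[1] + len(cand[2]))
        avail = jx[lo:middle_end]
        p = _p_extension(avail[::-1], revcomp(j5)[::-1])
        j_p = avail[len(avail) - p:] if p else ""

    if cand is None:
        n1 = jx[middle_start + len(v_p):middle_end - len(j_p)]
        return JunctionDecomposition(
            v_len=v_len, j_len=j_len, v_trim=v_trim, j_trim=j_trim,
            v_p=v_p, j_p=j_p, n1=n1,
            v_match=jx[:v_len], j_match=jx[L - j_len:])

    name, off, window, _idx, d5_trim, d3_trim, d_seq = cand
    d_start = middle_start + off
    d_end = d_start + len(window)
    # P at the D ends (only on untrimmed ends, inside the N gaps)
    d5_p = ""
    if d5_trim == 0:
        gap = jx[middle_start + len(v_p):d_start]
        p = _p_extension(gap[::-1], revcomp(d_seq)[::-1])
        d5_p = gap[len(gap) - p:] if p else ""
    d3_p = ""
    if d3_trim == 0:
        gap = jx[d_end:middle_end - len(j_p)]
        p = _p_extension(gap, revcomp(d_seq))
        d3_p = gap[:p]
    n1 = jx[middle_start + len(v_p):d_start - len(d5_p)]
    n2 = jx[d_end + len(d3_p):middle_end - len(j_p)]
    return JunctionDecomposition(
        v_len=v_len, j_len=j_len, d_len=len(window), d_call=name,
        v_trim=v_trim, d5_trim=d5_trim, d3_trim=d3_trim, j_trim=j_trim,
        v_p=v_p, d5_p=d5_p, d3_p=d3_p, j_p=j_p, n1=n1, n2=n2,
        v_match=jx[:v_len], d_match=window, j_match=jx[L - j_len:])


# --------------------------------------------------------------------------
# decryption string


def _end_mark(trim: int, p: str) -> str:
    if trim > 0:
        return f"-{trim}"
    if p:
        return f"+{len(p)}"
    return ""


def format_decryption(d: JunctionDecomposition) -> str:
    """Compact 5'->3' notation of a decomposition.

    Germline segment lengths in parentheses, N lengths in braces, trims as
    negative and P as positive integers at the coding ends; zero marks are
    omitted.  Example: ``(7)-2{3}(5){2}(15)``.
    """
    parts = [f"({d.v_len})", _end_mark(d.v_trim, d.v_p)]
    if d.has_d:
        parts += [f"{{{len(d.n1)}}}", _end_mark(d.d5_trim, d.d5_p),
                  f"({d.d_len})", _end_mark(d.d3_trim, d.d3_p),
                  f"{{{len(d.n2)}}}"]
    else:
        parts += [f"{{{len(d.n1)}}}"]
    parts += [_end_mark(d.j_trim, d.j_p), f"({d.j_len})"]
    return "".join(parts)


_TOKEN = re.compile(r"\((\d+)\)|\{(\d+)\}|([+-]\d+)")


def parse_decryption(s: str) -> JunctionDecomposition:
    """Parse a decryption string into a lengths-only decomposition.

    Sequence fields are left empty; P lengths are represented by
    placeholder strings of matching length so the structural accessors
    (:func:`format_decryption` round trip, trim counts) are preserved.
    """
    tokens = []
    pos = 0
    for m in _TOKEN.finditer(s):
        if m.start() != pos:
            raise JunctionError(
                f"malformed decryption string at offset {pos}: {s!r}")
        if m.group(1) is not None:
            tokens.append(("seg", int(m.group(1))))
        elif m.group(2) is not None:
            tokens.append(("n", int(m.group(2))))
        else:
            tokens.append(("mark", int(m.group(3))))
        pos = m.end()
    if pos != len(s):
        raise JunctionError(
            f"malformed decryption string at offset {pos}: {s!r}")
    segs = [t for t in tokens if t[0] == "seg"]
    ns = [t for t in tokens if t[0] == "n"]
    if len(segs) == 3 and len(ns) == 2:
        order = ["seg", "mark?", "n", "mark?", "seg", "mark?", "n",
                 "mark?", "seg"]
    elif len(segs) == 2 and len(ns) == 1:
        order = ["seg", "mark?", "n", "mark?", "seg"]
    else:
        raise JunctionError(f"unrecognized decryption shape: {s!r}")
    values = _match_shape(tokens, order, s)
    if len(segs) == 3:
        v_len, vm, n1, d5m, d_len, d3m, n2, jm, j_len = values
        return JunctionDecomposition(
            v_len=v_len, j_len=j_len, d_len=d_len, d_call="D",
            v_trim=max(0, -vm), d5_trim=max(0, -d5m),
            d3_trim=max(0, -d3m), j_trim=max(0, -jm),
            v_p="p" * max(0, vm), d5_p="p" * max(0, d5m),
            d3_p="p" * max(0, d3m), j_p="p" * max(0, jm),
            n1="n" * n1, n2="n" * n2)
    v_len, vm, n1, jm, j_len = values
    return JunctionDecomposition(
        v_len=v_len, j_len=j_len,
        v_trim=max(0, -vm), j_trim=max(0, -jm),
        v_p="p" * max(0, vm), j_p="p" * max(0, jm), n1="n" * n1)


def _match_shape(tokens, order, s):
    values = []
    ti = 0
    for slot in order:
        optional = slot.endswith("?")
        kind = slot.rstrip("?")
        if ti < len(tokens) and tokens[ti][0] == kind:
            values.append(tokens[ti][1])
            ti += 1
        elif optional:
            values.append(0)
        else:
            raise JunctionError(f"malformed decryption string: {s!r}")
    if ti != len(tokens):
        raise JunctionError(f"malformed decryption string: {s!r}")
    return values
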