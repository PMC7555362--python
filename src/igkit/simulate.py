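"""Synthetic germline sets and V-(D)-J rearrangement simulation.

The simulator emulates the molecular steps that create junctional
diversity: D-J joining followed by V-DJ joining, exonucleolytic trimming
of the coding ends (geometric lengths), P-nucleotide addition at
untrimmed ends (1-3 nt palindromes of the intact coding end), and
template-independent N-nucleotide insertion with a configurable bias
toward 'g'.  Somatic hypermutation is modelled as per-site point
mutations with mutability upweighted inside the classical hotspot motifs
(a/t)a, t(a/t), (a/g)g(c/t)(a/t) and (a/t)(a/g)c(c/t), and transitions
favoured 2:1 over transversions.

Toy germline genes are generated so that every V encodes the conserved
C23, W41, hydrophobic 89 and C104 at the correct gapped positions and
every J encodes the F/W-G-X-G motif; generated domains therefore pass
hallmark verification by construction.

Every emitted record carries its full ground truth (chosen genes, trims,
P segments, N regions, mutated sites, clone id) so downstream modules
can be tested end to end.  All randomness flows from one seed;
identical configurations are reproducible byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .junction import revcomp
from .numbering import V_TOPOLOGY, assign_numbering

__all__ = [
    "SimConfig",
    "ToyGermline",
    "SimRecord",
    "make_toy_germline",
    "simulate_repertoire",
    "repertoire_to_frame",
]

# one unambiguous codon per amino acid keeps translation round trips exact
_CODON = {
    "A": "gct", "C": "tgt", "D": "gat", "E": "gaa", "F": "ttt",
    "G": "ggt", "H": "cat", "I": "att", "K": "aaa", "L": "ctg",
    "M": "atg", "N": "aat", "P": "cct", "Q": "caa", "R": "cgt",
    "S": "agc", "T": "act", "V": "gtt", "W": "tgg", "Y": "tat",
}
_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "acgt"
_TRANSITION = {"a": "g", "g": "a", "c": "t", "t": "c"}

# hotspot motifs as (pattern, index of the mutable position);
# classes: w = a/t, r = a/g, y = c/t
_HOTSPOT_MOTIFS = [
    ("wa", 1),
    ("tw", 0),
    ("rgyw", 1),
    ("wrcy", 2),
]
_CLASS = {"w": "at", "r": "ag", "y": "ct", "a": "a", "c": "c",
          "g": "g", "t": "t"}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one simulated repertoire.

    Trim lengths are geometric with mean ``trim_mean``; N lengths are
    Poisson with mean ``n_mean`` and composition P(g) = ``g_bias`` (the
    other three nucleotides equiprobable); P nucleotides appear with
    probability ``p_prob`` at each untrimmed coding end, length uniform
    on 1-3.  ``shm_rate`` is the per-nucleotide mutation probability
    outside hotspots; hotspot positions are upweighted by
    ``hotspot_multiplier``.  SHM is kept out of the junction unless
    ``shm_in_junction`` is set.
    """

    seed: int = 0
    n_v: int = 5
    n_d: int = 4
    n_j: int = 3
    trim_mean: float = 2.0
    p_prob: float = 0.5
    n_mean: float = 4.0
    g_bias: float = 0.4
    shm_rate: float = 0.0
    hotspot_multiplier: float = 5.0
    shm_in_junction: bool = False
    n_clones: int = 20
    clone_size_mean: float = 5.0

    def __post_init__(self) -> None:
        for name in ("p_prob", "g_bias"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 <= self.shm_rate <= 1.0:
            raise ValueError("shm_rate must be in [0, 1]")
        if min(self.n_v, self.n_d, self.n_j) < 1:
            raise ValueError("germline sizes must be >= 1")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")


@dataclass(frozen=True)
class ToyGermline:
    """Toy V/D/J sets: full nucleotide genes plus junction-region views."""

    v_genes: dict        # name -> full V nt (codons 1..104 + 3' tail)
    d_genes: dict        # name -> D nt
    j_genes: dict        # name -> full J nt (5' tail + codons 118..128)
    v3_refs: dict        # name -> junction view: codon 104 + 3' tail
    j5_refs: dict        # name -> junction view: 5' tail + codon 118
    v_aa_boundaries: tuple = (25, 8, 17, 8, 38)   # FR1 CDR1 FR2 CDR2 FR3

    def to_fasta(self) -> str:
        lines = []
        for group in ("v_genes", "d_genes", "j_genes"):
            for name, seq in getattr(self, group).items():
                lines.append(f">{name}")
                lines.append(seq)
        return "\n".join(lines) + "\n"


def _random_aa(rng, n, exclude="C"):
    out = []
    choices = [a for a in _AA if a not in exclude]
    for _ in range(n):
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _codons(aa_seq: str) -> str:
    return "".join(_CODON[a] for a in aa_seq)


def make_toy_germline(config: SimConfig, rng=None) -> ToyGermline:
    """Generate toy germline V, D and J sets under the hallmark
    constraints (C23, W41, hydrophobic 89, C104 for V; F/W-G-X-G for J)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    hydrophobic = "IVLFMA"
    v_genes = {}
    v3_refs = {}
    for i in range(config.n_v):
        name = f"TOYV{i + 1}*01"
        # FR1 of 25 leaves the gap at 10, so position 23 is its 22nd residue
        fr1 = _random_aa(rng, 21) + "C" + _random_aa(rng, 3)
        cdr1 = _random_aa(rng, 8)
        fr2 = _random_aa(rng, 2) + "W" + _random_aa(rng, 14)      # W at 41
        cdr2 = _random_aa(rng, 8)
        # FR3 spans 66..104 with gap at 73 (38 aa); 89 is its 23rd residue
        # (66..72 then 74..89 -> 22 residues precede it)
        fr3 = (_random_aa(rng, 22)
               + hydrophobic[rng.integers(len(hydrophobic))]
               + _random_aa(rng, 14) + "C")                        # C at 104
        aa = fr1 + cdr1 + fr2 + cdr2 + fr3
        tail = "".join(_NT[rng.integers(4)] for _ in range(4 + rng.integers(4)))
        nt = _codons(aa) + tail
        v_genes[name] = nt
        v3_refs[name] = _CODON["C"] + tail      # junction starts at codon 104
    d_genes = {}
    for i in range(config.n_d):
        name = f"TOYD{i + 1}*01"
        length = 12 + int(rng.integers(9))
        d_genes[name] = "".join(_NT[rng.integers(4)] for _ in range(length))
    j_genes = {}
    j5_refs = {}
    for i in range(config.n_j):
        name = f"TOYJ{i + 1}*01"
        tail_len = 4 + int(rng.integers(7))
        tail = "".join(_NT[rng.integers(4)] for _ in range(tail_len))
        aa118 = "FW"[rng.integers(2)]
        fr4 = aa118 + "G" + _random_aa(rng, 1) + "G" + _random_aa(rng, 7)
        j5_refs[name] = tail + _CODON[aa118]
        j_genes[name] = tail + _codons(fr4)
    return ToyGermline(v_genes=v_genes, d_genes=d_genes, j_genes=j_genes,
                       v3_refs=v3_refs, j5_refs=j5_refs)


@dataclass
class SimRecord:
    """One simulated rearrangement with its ground truth."""

    sequence_id: str
    clone_id: int
    sequence: str
    v_call: str
    d_call: str
    j_call: str
    junction: str
    junction_aa: str
    cdr3_aa: str
    cdr3_nt: str
    truth: dict
    shm_positions: tuple = ()
    nondegenerate: bool = True

    @property
    def productive(self) -> bool:
        return "*" not in self.junction_aa


def _geometric(rng, mean: float) -> int:
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (1.0 + mean)) - 1)


def _draw_n(rng, length: int, g_bias: float) -> str:
    out = []
    for _ in range(length):
        if rng.random() < g_bias:
            out.append("g")
        else:
            out.append("act"[rng.integers(3)])
    return "".join(out)


def _plan_junction(rng, config, v3, d_seq, j5):
    """Draw trims, P and N segments; returns the part dict."""
    # codon 104 and codon 118 must stay intact
    v_trim = min(_geometric(rng, config.trim_mean), len(v3) - 3)
    j_trim = min(_geometric(rng, config.trim_mean), len(j5) - 3)
    d5_trim = min(_geometric(rng, config.trim_mean), len(d_seq) // 2)
    d3_trim = min(_geometric(rng, config.trim_mean),
                  len(d_seq) - d5_trim - 5)
    d3_trim = max(d3_trim, 0)

    def maybe_p(trimmed: int) -> int:
        if trimmed == 0 and rng.random() < config.p_prob:
            return 1 + int(rng.integers(3))
        return 0

    v_p_len = maybe_p(v_trim)
    j_p_len = maybe_p(j_trim)
    d5_p_len = maybe_p(d5_trim)
    d3_p_len = maybe_p(d3_trim)

    v_match = v3[: len(v3) - v_trim]
    d_match = d_seq[d5_trim: len(d_seq) - d3_trim]
    j_match = j5[j_trim:]
    v_p = revcomp(v3)[:v_p_len] if v_p_len else ""
    d5_p = revcomp(d_seq[:d5_p_len]) if d5_p_len else ""
    d3_p = revcomp(d_seq[len(d_seq) - d3_p_len:]) if d3_p_len else ""
    j_p = revcomp(j5[:j_p_len]) if j_p_len else ""

    n1 = _draw_n(rng, rng.poisson(config.n_mean), config.g_bias)
    n2 = _draw_n(rng, rng.poisson(config.n_mean), config.g_bias)
    # keep the junction in frame (codon 104 .. codon 118)
    total = (len(v_match) + len(v_p) + len(n1) + len(d5_p) + len(d_match)
             + len(d3_p) + len(n2) + len(j_p) + len(j_match))
    pad = (-total) % 3
    n2 += _draw_n(rng, pad, config.g_bias)
    return {
        "v_match": v_match, "v_p": v_p, "n1": n1, "d5_p": d5_p,
        "d_match": d_match, "d3_p": d3_p, "n2": n2, "j_p": j_p,
        "j_match": j_match, "v_trim": v_trim, "d5_trim": d5_trim,
        "d3_trim": d3_trim, "j_trim": j_trim,
    }


def _hotspot_mask(seq: str) -> np.ndarray:
    mask = np.zeros(len(seq), dtype=bool)
    for motif, hot in _HOTSPOT_MOTIFS:
        w = len(motif)
        for i in range(len(seq) - w + 1):
            if all(seq[i + k] in _CLASS[motif[k]] for k in range(w)):
                mask[i + hot] = True
    return mask


def _apply_shm(rng, seq: str, config: SimConfig, protect: range):
    if config.shm_rate <= 0:
        return seq, ()
    mask = _hotspot_mask(seq)
    rates = np.full(len(seq), config.shm_rate)
    rates[mask] = np.minimum(config.shm_rate * config.hotspot_multiplier,
                             0.95)
    out = list(seq)
    mutated = []
    for i in range(len(seq)):
        if not config.shm_in_junction and i in protect:
            continue
        if rng.random() < rates[i]:
            base = out[i]
            if rng.random() < 2.0 / 3.0:
                out[i] = _TRANSITION[base]
            else:
                others = [b for b in _NT if b not in (base, _TRANSITION[base])]
                out[i] = others[rng.integers(2)]
            if out[i] != base:
                mutated.append(i)
    return "".join(out), tuple(mutated)


def _check_nondegenerate(parts, v3, d_seq, j5, d_genes, min_d=5) -> bool:
    """True when the planted decomposition is the unique optimum that a
    germline-match-maximizing analysis can recover (string checks only)."""
    junction = (parts["v_match"] + parts["v_p"] + parts["n1"] + parts["d5_p"]
                + parts["d_match"] + parts["d3_p"] + parts["n2"]
                + parts["j_p"] + parts["j_match"])
    v_len = len(parts["v_match"])
    j_len = len(parts["j_match"])
    # planted V/J matches must be maximal and not extendable
    lcp = 0
    for a, b in zip(junction, v3):
        if a != b:
            break
        lcp += 1
    if lcp != v_len:
        return False
    lcs = 0
    for a, b in zip(junction[::-1], j5[::-1]):
        if a != b:
            break
        lcs += 1
    if lcs != j_len:
        return False
    # no spurious or extendable P at the V/J ends
    after_v = junction[v_len:]
    expected_vp = revcomp(v3)
    if parts["v_trim"] == 0:
        k = len(parts["v_p"])
        if k < 3 and after_v[k: k + 1] == expected_vp[k: k + 1]:
            return False
    before_j = junction[: len(junction) - j_len]
    expected_jp = revcomp(j5)
    if parts["j_trim"] == 0:
        k = len(parts["j_p"])
        if k < 3 and before_j[-k - 1: len(before_j) - k] == \
                expected_jp[-k - 1: len(expected_jp) - k]:
            return False
    # planted D window must be the unique best match in the middle
    middle = junction[v_len: len(junction) - j_len]
    d_len = len(parts["d_match"])
    if d_len < min_d:
        return False
    planted_at = (len(parts["v_p"]) + len(parts["n1"]) + len(parts["d5_p"]))
    best = 0
    hits = []
    for name, seq in d_genes.items():
        for wlen in range(min(len(seq), len(middle)), min_d - 1, -1):
            found_here = False
            for start in range(len(seq) - wlen + 1):
                window = seq[start:start + wlen]
                off = middle.find(window)
                while off != -1:
                    found_here = True
                    hits.append((wlen, name, off, start))
                    off = middle.find(window, off + 1)
            if found_here:
                break
    if not hits:
        return False
    best = max(h[0] for h in hits)
    top = [h for h in hits if h[0] == best]
    if len(top) != 1:
        return False
    wlen, name, off, start = top[0]
    if (wlen != d_len or seqs_differ(d_genes[name], d_seq)
            or off != planted_at):
        return False
    # no spurious P at the D ends
    if parts["d5_trim"] == 0:
        k = len(parts["d5_p"])
        gap = middle[len(parts["v_p"]):planted_at - k] if k else \
            middle[len(parts["v_p"]):planted_at]
        exp = revcomp(d_seq[k: k + 1])
        if k < 3 and gap[-1:] == exp:
            return False
    if parts["d3_trim"] == 0:
        k = len(parts["d3_p"])
        after_d = middle[planted_at + d_len + k:]
        exp = revcomp(d_seq[-k - 1:])[: 1] if k else revcomp(d_seq)[:1]
        if k < 3 and after_d[:1] == exp:
            return False
    return True


def seqs_differ(a: str, b: str) -> bool:
    return a != b


def simulate_repertoire(config: SimConfig, germline: ToyGermline | None = None
                        ) -> list:
    """Simulate a clonal repertoire; returns a list of :class:`SimRecord`.

    D-J joining precedes V-DJ joining; every record of a clone shares the
    rearrangement (and junction) and differs only by SHM.
    """
    rng = np.random.default_rng(config.seed)
    if germline is None:
        germline = make_toy_germline(config, rng)
    v_names = sorted(germline.v_genes)
    d_names = sorted(germline.d_genes)
    j_names = sorted(germline.j_genes)
    records = []
    seq_no = 0
    seen_keys = set()
    for clone_id in range(1, config.n_clones + 1):
        for _attempt in range(200):
            v = v_names[rng.integers(len(v_names))]
            d = d_names[rng.integers(len(d_names))]
            j = j_names[rng.integers(len(j_names))]
            parts = _plan_junction(
                rng, config, germline.v3_refs[v], germline.d_genes[d],
                germline.j5_refs[j])
            junction = (parts["v_match"] + parts["v_p"] + parts["n1"]
                        + parts["d5_p"] + parts["d_match"] + parts["d3_p"]
                        + parts["n2"] + parts["j_p"] + parts["j_match"])
            junction_aa = str(Seq(junction).translate())
            key = (v.split("*")[0], j.split("*")[0], junction_aa[1:-1])
            # clones must be separable by their defining key
            if "*" not in junction_aa and key not in seen_keys:
                seen_keys.add(key)
                break
        nondegenerate = _check_nondegenerate(
            parts, germline.v3_refs[v], germline.d_genes[d],
            germline.j5_refs[j], germline.d_genes)
        v_full = germline.v_genes[v]
        j_full = germline.j_genes[j]
        pre = v_full[: len(v_full) - len(germline.v3_refs[v])]
        post = j_full[len(germline.j5_refs[j]):]
        base_seq = pre + junction + post
        jx_span = range(len(pre), len(pre) + len(junction))
        size = 1 + int(rng.poisson(max(config.clone_size_mean - 1, 0)))
        for _ in range(size):
            seq_no += 1
            mutated, shm_pos = _apply_shm(rng, base_seq, config, jx_span)
            mut_junction = mutated[len(pre): len(pre) + len(junction)]
            mut_junction_aa = str(Seq(mut_junction).translate())
            records.append(SimRecord(
                sequence_id=f"SIM{seq_no:06d}",
                clone_id=clone_id,
                sequence=mutated,
                v_call=v, d_call=d, j_call=j,
                junction=mut_junction,
                junction_aa=mut_junction_aa,
                cdr3_aa=mut_junction_aa[1:-1],
                cdr3_nt=mut_junction[3:-3],
                truth={
                    "v_call": v, "d_call": d, "j_call": j,
                    "v_len": len(parts["v_match"]),
                    "d_len": len(parts["d_match"]),
                    "j_len": len(parts["j_match"]),
                    "v_trim": parts["v_trim"],
                    "d5_trim": parts["d5_trim"],
                    "d3_trim": parts["d3_trim"],
                    "j_trim": parts["j_trim"],
                    "v_p": parts["v_p"], "d5_p": parts["d5_p"],
                    "d3_p": parts["d3_p"], "j_p": parts["j_p"],
                    "n1": parts["n1"], "n2": parts["n2"],
                    "junction": junction,
                },
                shm_positions=shm_pos,
                nondegenerate=nondegenerate and not (
                    config.shm_in_junction and shm_pos),
            ))
    return records


def repertoire_to_frame(records) -> pd.DataFrame:
    """AIRR-style rearrangement table for a simulated repertoire."""
    rows = []
    for r in records:
        rows.append({
            "sequence_id": r.sequence_id,
            "sequence": r.sequence,
            "v_call": r.v_call,
            "d_call": r.d_call,
            "j_call": r.j_call,
            "junction": r.junction,
            "junction_aa": r.junction_aa,
            "cdr3_aa": r.cdr3_aa,
            "cdr3_nt": r.cdr3_nt,
            "productive": r.productive,
            "clone_id": r.clone_id,
            "v_identity_pct": round(
                100.0 * (1 - len(r.shm_positions) / max(len(r.sequence), 1)),
                2),
        })
    return pd.DataFrame(rows)


def truth_sidecar(records) -> str:
    """JSON ground-truth sidecar matching the rearrangement table."""
    payload = {
        r.sequence_id: {
            "clone_id": r.clone_id,
            "truth": r.truth,
            "shm_positions": list(r.shm_positions),
            "nondegenerate": r.nondegenerate,
        }
        for r in records
    }
    return json.dumps(payload, indent=1, sort_keys=True)
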