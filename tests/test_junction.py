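"""Junction decomposition: constructed cases, invariants and equivalence
of the optimisation objective with a naive enumerate-and-check oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igkit.junction import (
    JunctionDecomposition,
    JunctionError,
    decompose_junction,
    format_decryption,
    parse_decryption,
    revcomp,
)

MIN_D = 5


# --------------------------------------------------------------------------
# independent oracle: enumerate every decomposition, keep the best objective


def oracle_best_key(junction, v3, d_refs, j5, min_d=MIN_D):
    """Exhaustive search over all valid decompositions; returns the best
    (matched_total, p_total, d_len, -gene_index) objective tuple."""
    junction = junction.lower()
    v3 = v3.lower()
    j5 = j5.lower()
    d_items = [(n, s.lower()) for n, s in d_refs]
    L = len(junction)
    best = None

    def p_options(untrimmed, source_p):
        # 0 plus every palindrome length 1..3 of the intact coding end
        yield ""
        if untrimmed:
            for k in (1, 2, 3):
                if len(source_p) >= k:
                    yield source_p[:k]

    for v_len in range(0, min(len(v3), L) + 1):
        if junction[:v_len] != v3[:v_len]:
            continue
        v_trim = len(v3) - v_len
        for j_len in range(0, min(len(j5), L - v_len) + 1):
            if j_len and junction[-j_len:] != j5[-j_len:]:
                continue
            j_trim = len(j5) - j_len
            middle = junction[v_len:L - j_len]
            candidates = [None]
            for gi, (name, d_seq) in enumerate(d_items):
                for start in range(len(d_seq)):
                    for end in range(start + min_d, len(d_seq) + 1):
                        window = d_seq[start:end]
                        off = middle.find(window)
                        while off != -1:
                            candidates.append(
                                (gi, name, d_seq, start, end, off))
                            off = middle.find(window, off + 1)
            for cand in candidates:
                for v_p in p_options(v_len and v_trim == 0, revcomp(v3)):
                    if not middle.startswith(v_p):
                        continue
                    for j_p in p_options(j_len and j_trim == 0,
                                         revcomp(j5)[::-1]):
                        j_p = j_p[::-1]
                        if j_p and not middle.endswith(j_p):
                            continue
                        if cand is None:
                            if len(v_p) + len(j_p) > len(middle):
                                continue
                            key = (v_len + j_len, len(v_p) + len(j_p), 0, 0)
                            best = key if best is None else max(best, key)
                            continue
                        gi, name, d_seq, start, end, off = cand
                        d_len = end - start
                        if off < len(v_p) or off + d_len > \
                                len(middle) - len(j_p):
                            continue
                        for d5_p in p_options(start == 0,
                                              revcomp(d_seq[:3])[::-1]):
                            d5_p = d5_p[::-1][: 3]
                            d5_p = d5_p[-min(3, len(d5_p)):]
                            if d5_p and middle[off - len(d5_p):off] != d5_p:
                                continue
                            if d5_p and off - len(d5_p) < len(v_p):
                                continue
                            for d3_p in p_options(
                                    end == len(d_seq), revcomp(d_seq)):
                                if d3_p and middle[
                                        off + d_len:
                                        off + d_len + len(d3_p)] != d3_p:
                                    continue
                                if d3_p and off + d_len + len(d3_p) > \
                                        len(middle) - len(j_p):
                                    continue
                                key = (v_len + j_len + d_len,
                                       len(v_p) + len(j_p) + len(d5_p)
                                       + len(d3_p), d_len, -gi)
                                best = key if best is None else \
                                    max(best, key)
    return best


def impl_key(dec, d_refs):
    names = [n for n, _ in d_refs]
    gi = names.index(dec.d_call) if dec.d_call else 0
    p_total = (len(dec.v_p) + len(dec.d5_p) + len(dec.d3_p) + len(dec.j_p))
    return (dec.matched_total, p_total, dec.d_len, -gi)


def random_case(rng):
    def seq(n):
        return "".join("acgt"[rng.integers(4)] for _ in range(n))

    v3 = seq(6 + rng.integers(5))
    j5 = seq(6 + rng.integers(5))
    d_refs = [(f"D{i + 1}", seq(8 + rng.integers(7)))
              for i in range(1 + rng.integers(3))]
    # junction built from germline pieces plus random inserts
    v_keep = 3 + rng.integers(len(v3) - 2)
    j_keep = 3 + rng.integers(len(j5) - 2)
    d_name, d_seq = d_refs[rng.integers(len(d_refs))]
    d_lo = rng.integers(max(len(d_seq) - 6, 1))
    d_hi = min(len(d_seq), d_lo + 5 + rng.integers(6))
    junction = (v3[:v_keep] + seq(rng.integers(5)) + d_seq[d_lo:d_hi]
                + seq(rng.integers(5)) + j5[-j_keep:])
    return junction[:45], v3, d_refs, j5


class TestConstructedCases:
    def test_pure_germline_vj_identity(self):
        v3 = "tgtgcgagaga"
        j5 = "actactttgactactgg"
        dec = decompose_junction(v3 + j5, v3, [], j5)
        assert (dec.v_len, dec.j_len) == (len(v3), len(j5))
        assert dec.d_call is None
        assert dec.n1 == "" and dec.v_trim == 0 and dec.j_trim == 0

    def test_pure_germline_vdj(self):
        v3 = "tgtgcgagaga"
        d = "gggtagtggttatta"
        j5 = "actactttgactactgg"
        dec = decompose_junction(v3 + d + j5, v3, [("D2-2", d)], j5)
        assert dec.d_call == "D2-2"
        assert (dec.v_len, dec.d_len, dec.j_len) == (11, 15, 17)
        assert dec.n1 == "" and dec.n2 == ""

    def test_p_nucleotides_at_intact_v_end(self):
        # intact V end ...cgtc followed by "ga" = revcomp("tc")
        v3 = "tgcacgtc"
        j5 = "actactttgactactgg"
        junction = v3 + "ga" + "aaat" + j5[2:]
        dec = decompose_junction(junction, v3, [], j5)
        assert dec.v_trim == 0
        assert dec.v_p == "ga"
        assert dec.j_trim == 2

    def test_trim_and_p_mutually_exclusive(self):
        with pytest.raises(JunctionError):
            JunctionDecomposition(v_len=5, j_len=5, v_trim=2, v_p="ga")

    def test_short_junction_rejected(self):
        with pytest.raises(JunctionError):
            decompose_junction("acgta", "acgta", [], "acgta")


class TestDecryptionString:
    def test_plain_lengths_form(self):
        dec = JunctionDecomposition(
            v_len=7, j_len=15, d_len=5, d_call="D1",
            n1="ggc", n2="ta", v_match="a" * 7, d_match="c" * 5,
            j_match="t" * 15)
        assert format_decryption(dec) == "(7){3}(5){2}(15)"

    def test_trim_rendered_negative(self):
        dec = JunctionDecomposition(v_len=7, j_len=15, v_trim=2, n1="ggc")
        assert format_decryption(dec).startswith("(7)-2{3}")

    def test_p_rendered_positive(self):
        dec = JunctionDecomposition(v_len=7, j_len=15, v_p="ga", n1="ggc")
        assert format_decryption(dec).startswith("(7)+2{3}")

    def test_parse_lengths(self):
        dec = parse_decryption("(7){3}(5){2}(15)")
        assert (dec.v_len, len(dec.n1), dec.d_len, len(dec.n2),
                dec.j_len) == (7, 3, 5, 2, 15)

    def test_format_parse_round_trip(self):
        for s in ("(7){3}(5){2}(15)", "(7)-2{3}(5)+1{2}-3(15)",
                  "(11)+2{4}-1(15)", "(8){0}(17)"):
            assert format_decryption(parse_decryption(s)) == s

    def test_malformed_strings_rejected(self):
        for bad in ("(7}{3}", "7{3}", "(7){3", "(7)x{3}", ""):
            with pytest.raises(JunctionError):
                parse_decryption(bad)


class TestOracleEquivalence:
    def test_objective_matches_brute_force_on_random_junctions(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            junction, v3, d_refs, j5 = random_case(rng)
            if len(junction) < 6:
                continue
            dec = decompose_junction(junction, v3, d_refs, j5)
            assert dec.reconstruct() == junction.lower()
            assert impl_key(dec, d_refs) == oracle_best_key(
                junction, v3, d_refs, j5)

    def test_reconstruction_invariant_and_p_validity(self):
        rng = np.random.default_rng(7)
        for _ in range(80):
            junction, v3, d_refs, j5 = random_case(rng)
            dec = decompose_junction(junction, v3, d_refs, j5)
            assert dec.reconstruct() == junction.lower()
            if dec.v_p:
                assert dec.v_trim == 0
                assert dec.v_p == revcomp(v3.lower())[: len(dec.v_p)]
            if dec.j_p:
                assert dec.j_trim == 0
                assert dec.j_p == revcomp(j5.lower())[-len(dec.j_p):]

    def test_monotonicity_appending_germline_never_decreases_match(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            junction, v3, d_refs, j5 = random_case(rng)
            base = decompose_junction(junction, v3, d_refs, j5)
            # extend the junction with more matching germline J
            longer_j5 = j5 + "ac"
            extended = junction + "ac"
            more = decompose_junction(extended, v3, d_refs, longer_j5)
            assert more.matched_total >= base.matched_total


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_decomposition_is_deterministic(seed):
    rng = np.random.default_rng(seed)
    junction, v3, d_refs, j5 = random_case(rng)
    a = decompose_junction(junction, v3, d_refs, j5)
    b = decompose_junction(junction, v3, d_refs, j5)
    assert a == b
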