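import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igkit.numbering import (
    ImgtPosition,
    LowConfidenceError,
    TopologyError,
    V_TOPOLOGY,
    C_TOPOLOGY,
    assign_numbering,
    cdr3_position_sequence,
    delimit_regions,
    infer_boundaries,
    loop_position_sequence,
    region_identity,
    verify_hallmarks,
)
from conftest import build_c_domain, build_vh


def strs(positions):
    return [str(p) for p in positions]


class TestImgtPosition:
    def test_insertion_block_order(self):
        order = ["111", "111.1", "111.2", "112.2", "112.1", "112"]
        parsed = [ImgtPosition.parse(s) for s in order]
        assert parsed == sorted(parsed)

    def test_turn_suborder_ascends_after_base(self):
        order = ["15", "15.1", "15.2", "15.3", "16"]
        parsed = [ImgtPosition.parse(s) for s in order]
        assert parsed == sorted(parsed)

    def test_serialization_round_trip(self):
        for text in ("111.2", "45.3", "84.4", "15.1", "96.1", "104"):
            assert str(ImgtPosition.parse(text)) == text

    def test_bounds(self):
        with pytest.raises(ValueError):
            ImgtPosition(0)
        with pytest.raises(ValueError):
            ImgtPosition(129)
        with pytest.raises(ValueError):
            ImgtPosition(111, 0)


class TestCdr3PositionSequence:
    def test_canonical_thirteen(self):
        assert strs(cdr3_position_sequence(13)) == [
            str(b) for b in range(105, 118)]

    def test_first_added_subposition_is_112_1(self):
        assert strs(cdr3_position_sequence(14)) == [
            "105", "106", "107", "108", "109", "110", "111",
            "112.1", "112", "113", "114", "115", "116", "117"]

    def test_gap_order_removes_111_then_112(self):
        assert strs(cdr3_position_sequence(11)) == [
            "105", "106", "107", "108", "109", "110",
            "113", "114", "115", "116", "117"]

    def test_length_21_reaches_fourth_subpositions(self):
        got = set(strs(cdr3_position_sequence(21)))
        for k in range(1, 5):
            assert f"111.{k}" in got
            assert f"112.{k}" in got

    def test_zero_and_negative_rejected(self):
        for bad in (0, -1):
            with pytest.raises(TopologyError):
                cdr3_position_sequence(bad)

    @pytest.mark.parametrize("n", range(1, 41))
    def test_length_and_strict_order(self, n):
        seq = cdr3_position_sequence(n)
        assert len(seq) == n
        assert all(a < b for a, b in zip(seq, seq[1:]))

    def test_nesting_of_gap_and_insertion_orders(self):
        for n in range(1, 40):
            m = n + 1
            if m <= 13 or n >= 13:
                smaller = set(cdr3_position_sequence(n))
                bigger = set(cdr3_position_sequence(m))
                assert smaller < bigger


class TestLoopPositionSequence:
    def test_full_loops_are_complete_ranges(self):
        assert strs(loop_position_sequence("BC", 12)) == [
            str(b) for b in range(27, 39)]
        assert strs(loop_position_sequence("C'C''", 10)) == [
            str(b) for b in range(56, 66)]

    def test_bc_length_8_apex_alternation(self):
        # hand application of the removal order 33, 32, 34, 31
        assert strs(loop_position_sequence("BC", 8)) == [
            "27", "28", "29", "30", "35", "36", "37", "38"]

    def test_overlong_loop_rejected(self):
        with pytest.raises(TopologyError):
            loop_position_sequence("BC", 13)
        with pytest.raises(TopologyError):
            loop_position_sequence("C'C''", 11)


class TestAssignNumbering:
    def test_canonical_vh_has_120_unique_positions(self, vh_domain):
        assert len(vh_domain.residues) == 120
        assert len(set(vh_domain.positions)) == 120

    def test_fr1_of_25_leaves_gap_at_10(self, vh_domain):
        assert ImgtPosition(10) in vh_domain.gaps
        assert vh_domain.aa_at(ImgtPosition(10)) is None

    def test_round_trip_strip_and_renumber(self, vh_domain):
        again = assign_numbering(vh_domain.sequence, vh_domain.boundaries,
                                 V_TOPOLOGY)
        assert again == vh_domain

    def test_segment_length_out_of_bounds(self):
        with pytest.raises(TopologyError):
            assign_numbering("A" * 119, (24, 8, 17, 8, 38, 13, 11),
                             V_TOPOLOGY)

    def test_c_domain_turns_fill_ascending(self, c_domain):
        positions = set(strs(c_domain.positions))
        assert {"15.1", "15.2"} <= positions
        assert {"45.1", "45.5"} <= positions
        # DE turn of 4: 84.1, 84.2 then 85.2, 85.1
        assert {"84.1", "84.2", "85.1", "85.2"} <= positions
        assert "84.3" not in positions

    def test_c_domain_bc_loop_lacks_32_and_33(self, c_domain):
        positions = set(strs(c_domain.positions))
        assert "31" in positions and "34" in positions
        assert "32" not in positions and "33" not in positions


class TestDelimitRegions:
    def test_vh_8_8_13_notation(self, vh_domain):
        delim = delimit_regions(vh_domain)
        assert delim.cdr_notation == "[8.8.13]"
        assert delim.fr_notation == "[25.17.38.11]"
        assert sum(delim.fr_lengths) == 91

    def test_vkappa_6_3_9(self):
        dom = build_vh(cdr_lengths=(6, 3, 9), fr_lengths=(26, 17, 36, 10))
        delim = delimit_regions(dom)
        assert delim.cdr_notation == "[6.3.9]"
        assert sum(delim.fr_lengths) == 89

    def test_junction_is_two_longer_than_cdr3(self):
        for c3 in (5, 9, 13, 17, 22):
            dom = build_vh(cdr_lengths=(8, 8, c3))
            delim = delimit_regions(dom)
            assert delim.junction_length - delim.cdr_lengths[2] == 2

    def test_c_domain_is_rejected(self, c_domain):
        with pytest.raises(ValueError):
            delimit_regions(c_domain)


class TestHallmarks:
    def test_all_pass_on_conforming_domain(self, vh_domain):
        report = verify_hallmarks(vh_domain)
        assert report["all_pass"]
        assert report[23]["observed"] == "C"
        assert report["J-MOTIF"]["status"] == "pass"

    def test_camelid_style_r118_flagged_not_fatal(self):
        dom = build_vh()
        seq = list(dom.sequence)
        idx = dom.positions.index(ImgtPosition(118))
        seq[idx] = "R"
        dom2 = assign_numbering("".join(seq), dom.boundaries, V_TOPOLOGY)
        report = verify_hallmarks(dom2)
        assert report[118]["status"] == "deviation"
        assert not report["all_pass"]
        assert report[23]["status"] == "pass"

    def test_missing_c104_reported(self):
        dom = build_vh()
        seq = list(dom.sequence)
        idx = dom.positions.index(ImgtPosition(104))
        seq[idx] = "S"
        report = verify_hallmarks(
            assign_numbering("".join(seq), dom.boundaries, V_TOPOLOGY))
        assert report[104]["status"] == "deviation"

    def test_anchor_flags_at_printed_positions(self, vh_domain, c_domain):
        v_anchors = {r.position.base for r in vh_domain.residues if r.anchor}
        assert v_anchors == {26, 39, 55, 66, 104, 118}
        c_anchors = {r.position.base for r in c_domain.residues if r.anchor}
        assert c_anchors == {26, 39, 45, 77, 104, 118}


class TestIdentityAndTransfer:
    def test_identical_domains_are_100(self, vh_domain):
        assert region_identity(vh_domain, vh_domain, "all") == 100.0

    def test_one_mismatch_in_hundred(self, vh_domain):
        seq = list(vh_domain.sequence)
        # mutate a non-hallmark FR3 residue
        idx = vh_domain.positions.index(ImgtPosition(77))
        seq[idx] = "D" if seq[idx] != "D" else "E"
        other = assign_numbering("".join(seq), vh_domain.boundaries,
                                 V_TOPOLOGY)
        shared = len(vh_domain.residues)
        expected = round(100 * (shared - 1) / shared, 1)
        assert region_identity(other, vh_domain, "all") == expected

    def test_identity_requires_nonempty_region(self, vh_domain):
        dom = build_vh(cdr_lengths=(8, 0, 13), fr_lengths=(25, 17, 38, 11))
        with pytest.raises(ValueError):
            region_identity(dom, dom, "CDR2")

    def test_transfer_on_identical_sequence(self, vh_domain):
        boundaries, report = infer_boundaries(vh_domain.sequence, vh_domain)
        assert boundaries == vh_domain.boundaries
        assert report["identity"]["FR1"] == 100.0

    def test_deletion_inside_cdr1_shrinks_cdr1_only(self, vh_domain):
        residues = [r for r in vh_domain.residues]
        kept = [r.aa for r in residues
                if str(r.position) not in ("29", "30")]
        boundaries, _ = infer_boundaries("".join(kept), vh_domain)
        expected = list(vh_domain.boundaries)
        expected[1] -= 2
        assert boundaries == tuple(expected)

    def test_non_domain_input_raises_low_confidence(self, vh_domain):
        with pytest.raises(LowConfidenceError):
            infer_boundaries("QQQQPPPPAAAA" * 9, vh_domain)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=1, max_value=40),
       st.integers(min_value=1, max_value=40))
def test_cdr3_position_sets_nest_within_each_regime(n, m):
    if n > m or (n < 13 < m):
        return
    assert set(cdr3_position_sequence(n)) <= set(cdr3_position_sequence(m))
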