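"""Motif grammar scanners: zinc fingers, Sal-box, poly-Q, fuzzy motifs, pairs."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spalt import (
    ScanParams,
    SequenceRecord,
    find_motif,
    find_polyq,
    find_salbox,
    find_zinc_fingers,
    pair_fingers,
    scan_record,
)
from spalt.records import AlphabetError
from spalt.scan import ScanWarning

FINGER_21 = "CPDCGKAFTTKGNLKVHRRTH"  # C2H2 carrying the Sal-box
NOBOX_21 = "CGKCNRSFSDRSNLNRHMKTH"   # C2H2 without Sal-box


def rec(seq, rid="r"):
    return SequenceRecord(rid, rid, seq)


# ---------------------------------------------------------------- fingers

def test_no_cysteine_means_no_fingers():
    assert find_zinc_fingers(rec("AAAAAAA")) == []


def test_printed_salbox_finger_detected_with_flag():
    r = rec("A" * 10 + FINGER_21 + "A" * 10)
    hits = find_zinc_fingers(r)
    assert len(hits) == 1
    h = hits[0]
    assert h.zf_class == "C2H2"
    assert h.span == (10, 31)
    assert h.contains_salbox
    assert h.coordinating_positions == (10, 13, 26, 30)


def test_two_spaced_fingers_offset_by_spacing():
    r = rec(FINGER_21 + "A" * 50 + FINGER_21)
    hits = find_zinc_fingers(r)
    assert len(hits) == 2
    (h1, h2) = hits
    assert h1.span == (0, 21)
    assert h2.span == (71, 92)
    assert (h2.end - h2.start) == (h1.end - h1.start)


def test_c2hc_class_recognised():
    zf1 = "CPECGKSFSRLENLKTHIRSC"
    hits = find_zinc_fingers(rec("AA" + zf1 + "AA"))
    assert [h.zf_class for h in hits] == ["C2HC"]


def test_coordinating_residues_match_class():
    r = rec(FINGER_21 + "A" * 30 + "CPECGKSFSRLENLKTHIRSC")
    for h in find_zinc_fingers(r):
        s = r.residues
        p1, p2, p3, p4 = h.coordinating_positions
        assert s[p1] == s[p2] == "C"
        assert s[p3] == "H"
        assert s[p4] == ("H" if h.zf_class == "C2H2" else "C")
        assert h.span[0] <= p1 < p4 < h.span[1]


def test_alphabet_violation_reports_position():
    with pytest.raises(AlphabetError) as err:
        find_zinc_fingers(rec("ACDE*FG"))
    assert err.value.position == 4


# ---------------------------------------------------------------- salbox

def test_salbox_exact_hit():
    hits = find_salbox(rec("FTTKGNLK"), max_mismatch=0)
    assert [(h.span, h.mismatches) for h in hits] == [((0, 8), 0)]


def test_salbox_single_mismatch_tolerance():
    r = rec("FTTKGNLA")
    assert find_salbox(r, max_mismatch=0) == []
    hits = find_salbox(r, max_mismatch=1)
    assert [(h.span, h.mismatches) for h in hits] == [((0, 8), 1)]


def test_salbox_absent():
    assert find_salbox(rec("MMMMMMMM"), max_mismatch=0) == []


def test_salbox_overlap_prefers_fewer_mismatches():
    # exact box at 4; the shifted overlapping windows all have mismatches
    r = rec("AAAA" + "FTTKGNLK" + "AAAA")
    hits = find_salbox(r, max_mismatch=2)
    assert hits[0].span == (4, 12)
    assert hits[0].mismatches == 0
    for h in hits[1:]:
        assert h.start >= 12 or h.end <= 4


# ---------------------------------------------------------------- polyq

@pytest.mark.parametrize(
    "seq,expected",
    [
        ("QQQQQQ", [(0, 6)]),
        ("AAAAAA", []),
        ("QQQAQQQ", [(0, 7)]),     # fraction 6/7 >= 0.8
        ("QQQQQ", []),             # below min length
        ("AQQAAQQA", []),          # fraction too low everywhere
    ],
)
def test_polyq_definition(seq, expected):
    hits = find_polyq(rec(seq))
    assert [h.span for h in hits] == expected


def test_polyq_ends_on_q():
    for h in find_polyq(rec("AAQQQQQQAAAQQQQQQQA")):
        s = "AAQQQQQQAAAQQQQQQQA"
        assert s[h.start] == "Q" and s[h.end - 1] == "Q"


# ---------------------------------------------------------------- motifs

CONSENSUS = "SETSKLQQLVENID"


def test_pre_zf3_consensus_verbatim():
    r = rec("AAAA" + CONSENSUS + "AAAA")
    hits = find_motif(r, CONSENSUS, 0)
    assert [(h.span, h.mismatches) for h in hits] == [((4, 18), 0)]


def test_consensus_two_substitutions():
    mutated = "SETSKLAQLVENIA"
    hits = find_motif(rec(mutated), CONSENSUS, 2)
    assert [(h.span, h.mismatches) for h in hits] == [((0, 14), 2)]


def test_consensus_longer_than_window_warns_empty():
    with pytest.warns(ScanWarning):
        hits = find_motif(rec("AAAA"), CONSENSUS, 0, search_window=(0, 4))
    assert hits == []


def test_window_restricts_matches():
    r = rec(CONSENSUS + "A" * 10 + CONSENSUS)
    hits = find_motif(r, CONSENSUS, 0, search_window=(0, 20))
    assert [h.span for h in hits] == [(0, 14)]


# ---------------------------------------------------------------- pairing

def test_salbox_free_fingers_never_pair():
    r = rec(NOBOX_21 + "GSGSG" + NOBOX_21)
    scan = scan_record(r)
    assert scan.pairs == []


def test_linked_pair_assembled():
    r = rec(NOBOX_21 + "GSGSG" + FINGER_21)
    scan = scan_record(r)
    assert len(scan.pairs) == 1
    p = scan.pairs[0]
    assert p.degenerate_side == "none"
    assert p.n_finger.span == (0, 21)
    assert p.c_finger.span == (26, 47)
    assert p.link_span == (21, 26)
    assert p.salbox.start >= p.c_finger.start and p.salbox.end <= p.c_finger.end


def test_orphan_salbox_finger_is_lost_n():
    r = rec("A" * 30 + FINGER_21 + "A" * 5)
    scan = scan_record(r)
    assert len(scan.pairs) == 1
    assert scan.pairs[0].degenerate_side == "lost_N"
    assert scan.pairs[0].n_finger is None


def test_neighbour_beyond_max_link_not_paired():
    r = rec(NOBOX_21 + "A" * 13 + FINGER_21)
    scan = scan_record(r)
    assert scan.pairs[0].degenerate_side == "lost_N"


# ------------------------------------------------- brute-force oracle

_P_H2 = re.compile(r"C.{1,5}C.{10,14}H.{3,6}H")
_P_HC = re.compile(r"C.{1,5}C.{10,14}H.{3,6}C")


def _oracle_fingers(seq):
    """Exhaustive all-substrings matcher with the same overlap rules."""
    cands = []
    for s in range(len(seq)):
        for e in range(s + 1, len(seq) + 1):
            sub = seq[s:e]
            if _P_H2.fullmatch(sub):
                cands.append((s, e, "C2H2"))
            elif _P_HC.fullmatch(sub):
                cands.append((s, e, "C2HC"))
    cands.sort(key=lambda c: (c[0], -(c[1] - c[0]), c[2] != "C2H2"))
    chosen, cursor = [], 0
    for s, e, cls in cands:
        if s >= cursor:
            chosen.append((s, e, cls))
            cursor = e
    return chosen


def _oracle_salbox(seq, max_mismatch):
    cands = []
    for s in range(len(seq) - 7):
        mm = sum(1 for a, b in zip(seq[s:s + 8], "FTTKGNLK") if a != b)
        if mm <= max_mismatch:
            cands.append((s, s + 8, mm))
    chosen = []
    for s, e, mm in sorted(cands, key=lambda c: (c[2], c[0])):
        if all(e <= cs or s >= ce for cs, ce, _ in chosen):
            chosen.append((s, e, mm))
    return sorted(chosen)


def test_fingers_and_salbox_match_bruteforce_on_random_sequences(rng):
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    # bias toward C/H so fingers actually occur
    probs = np.ones(20)
    probs[letters == "C"] = 6
    probs[letters == "H"] = 6
    probs = probs / probs.sum()
    for _ in range(40):
        n = int(rng.integers(30, 200))
        seq = "".join(rng.choice(letters, size=n, p=probs))
        r = rec(seq)
        got = [(h.start, h.end, h.zf_class) for h in find_zinc_fingers(r)]
        assert got == _oracle_fingers(seq)
        for mm in (0, 1, 2):
            got_b = [(h.start, h.end, h.mismatches)
                     for h in find_salbox(r, max_mismatch=mm)]
            assert got_b == _oracle_salbox(seq, mm)


# ------------------------------------------------- invariants

@given(k=st.integers(min_value=0, max_value=30), data=st.data())
@settings(max_examples=40, deadline=None, derandomize=True)
def test_translation_equivariance(k, data):
    """Prefixing with background residues shifts every span by exactly k."""
    body = data.draw(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY",
                             min_size=10, max_size=80))
    base = scan_record(rec("M" + body))  # ensure non-empty valid seq
    shifted = scan_record(rec("A" * k + "M" + body))
    assert [(h.start + k, h.end + k, h.zf_class)
            for h in base.fingers] == [(h.start, h.end, h.zf_class)
                                       for h in shifted.fingers]
    # exact Sal-box hits shift rigidly (a fuzzy window may newly straddle
    # the prefix boundary, so only mismatch-0 hits are compared)
    assert [(h.start + k, h.end + k) for h in base.salboxes
            if h.mismatches == 0] == \
        [(h.start, h.end) for h in shifted.salboxes if h.mismatches == 0]


def test_scan_is_deterministic(canonical_protein):
    r = canonical_protein.record
    a = scan_record(r)
    b = scan_record(r)
    assert a.all_hits() == b.all_hits()
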