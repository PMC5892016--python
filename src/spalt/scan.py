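"""Primitive feature detection for the Sal-box protein grammar.

Sall (Spalt-like) transcription factors are built from a small set of
recognisable sequence features:

* **zinc fingers** of the C2H2 class (``C-x(1,5)-C-x(10,14)-H-x(3,6)-H``)
  and the C2HC class (same spacing, terminal C), each coordinated by four
  residues;
* the **Sal-box**, the 8-residue motif ``FTTKGNLK`` carried by the
  C-terminal finger of each paired zinc-finger domain;
* a **poly-Q** tract (glutamine-rich region between ZF1 and ZF2);
* short fuzzy **consensus motifs** — the 14-residue stretch conserved just
  N-terminal of the ZF3 pair (``SETSKLQQLVENID``) and a 12-residue
  N-terminal segment that recruits the NuRD deacetylase complex;
* **H/C-linked finger pairs**: two C2H2 fingers joined by a short spacer,
  the C-terminal one carrying the Sal-box.

All coordinates are 0-based, half-open.  Every scanner is deterministic:
overlaps are resolved leftmost-longest, with C2H2 preferred over C2HC on
identical spans, and fuzzy motifs keep the fewest-mismatch (then leftmost)
window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .records import ALPHABET, AlphabetError, SequenceRecord

SALBOX_CONSENSUS = "FTTKGNLK"
PRE_ZF3_CONSENSUS = "SETSKLQQLVENID"

#: Default 12-residue N-terminal NuRD-interaction consensus used by the
#: synthetic generator and the scanner.  The motif's length (12) is its
#: conserved property; this particular default spelling is an
#: implementation choice, supplied through configuration, not a curated
#: biological consensus.
DEFAULT_NURD_CONSENSUS = "MSRKTAKPVDLG"


class ScanWarning(UserWarning):
    """Non-fatal scanning condition (e.g. consensus longer than its window)."""


@dataclass(frozen=True)
class ScanParams:
    """Tunable parameters of the motif grammar.

    The zinc-finger spacing windows are standard C2H2 ranges wide enough to
    admit the Sal-box-bearing fingers; all bounds are configurable.
    """

    zf_gap1: tuple[int, int] = (1, 5)    # residues between the two Cys
    zf_gap2: tuple[int, int] = (10, 14)  # residues between Cys2 and His1
    zf_gap3: tuple[int, int] = (3, 6)    # residues between His1 and the last site
    salbox_consensus: str = SALBOX_CONSENSUS
    salbox_max_mismatch: int = 1         # reporting tolerance
    salbox_member_mismatch: int = 0      # tolerance for contains_salbox / pairing
    polyq_min_length: int = 6
    polyq_min_fraction: float = 0.8
    pre_zf3_consensus: str = PRE_ZF3_CONSENSUS
    pre_zf3_max_mismatch: int = 2
    pre_zf3_window: int = 40             # max gap between consensus end and pair start
    nurd_consensus: str = DEFAULT_NURD_CONSENSUS
    nurd_max_mismatch: int = 2
    nurd_window: int = 30                # N-terminal search window for NuRD motif
    max_link: int = 12                   # max H/C-link spacer between paired fingers
    zf3a_window: int = 40                # max gap ZF3 pair end -> associated finger


@dataclass(frozen=True)
class ZincFingerHit:
    """One zinc-finger match; ``coordinating_positions`` are the four
    Cys/His (or Cys) zinc-coordinating residue positions, ascending."""

    zf_class: str                        # "C2H2" or "C2HC"
    span: tuple[int, int]
    coordinating_positions: tuple[int, int, int, int]
    contains_salbox: bool = False

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    span: tuple[int, int]
    mismatches: int = 0

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]


@dataclass(frozen=True)
class PairedDomain:
    """An H/C-linked zinc-finger pair whose C-terminal finger carries the
    Sal-box.  ``degenerate_side`` records a missing finger: ``lost_N`` when
    only the Sal-box finger survives, ``lost_C`` when the classifier decides
    an orphan Sal-box-free finger stands where a pair is expected."""

    c_finger: ZincFingerHit
    salbox: MotifHit
    n_finger: Optional[ZincFingerHit] = None
    degenerate_side: str = "none"        # none | lost_N | lost_C

    @property
    def link_span(self) -> tuple[int, int]:
        if self.n_finger is None:
            return (self.c_finger.start, self.c_finger.start)
        return (self.n_finger.end, self.c_finger.start)

    @property
    def span(self) -> tuple[int, int]:
        start = self.n_finger.start if self.n_finger is not None else self.c_finger.start
        return (start, self.c_finger.end)

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]


def _check_alphabet(record: SequenceRecord) -> None:
    for i, ch in enumerate(record.residues):
        if ch not in ALPHABET:
            raise AlphabetError(record.id, i, ch)


def _hamming(window: str, consensus: str) -> int:
    return sum(1 for a, b in zip(window, consensus) if a != b)


def _select_fuzzy(candidates: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Resolve overlaps among (start, end, mismatches) windows: fewest
    mismatches first, leftmost on ties; accepted hits exclude overlaps."""
    chosen: list[tuple[int, int, int]] = []
    for s, e, mm in sorted(candidates, key=lambda c: (c[2], c[0])):
        if all(e <= cs or s >= ce for cs, ce, _ in chosen):
            chosen.append((s, e, mm))
    chosen.sort(key=lambda c: c[0])
    return chosen


def find_salbox(record: SequenceRecord, max_mismatch: int = 0,
                consensus: str = SALBOX_CONSENSUS) -> list[MotifHit]:
    """Find Sal-box occurrences within ``max_mismatch`` substitutions.

    Returns non-overlapping hits sorted by position; on overlap the window
    with fewer mismatches wins, leftmost on ties.
    """
    if max_mismatch < 0 or max_mismatch > 2:
        raise ValueError("max_mismatch must be in [0, 2]")
    _check_alphabet(record)
    return find_motif(record, consensus, max_mismatch, motif_name="SALBOX")


def find_motif(record: SequenceRecord, consensus: str, max_mismatch: int,
               search_window: Optional[tuple[int, int]] = None,
               motif_name: str = "MOTIF") -> list[MotifHit]:
    """Fuzzy fixed-length motif scan (Hamming distance ≤ ``max_mismatch``).

    ``search_window`` restricts matches to windows fully inside the given
    0-based half-open interval.  A consensus longer than the window yields
    no hits and a :class:`ScanWarning`.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    _check_alphabet(record)
    seq = record.residues
    k = len(consensus)
    lo, hi = (0, len(seq)) if search_window is None else search_window
    if search_window is not None and not (0 <= lo <= hi <= len(seq)):
        raise ValueError(f"search_window {search_window} outside sequence")
    if k > hi - lo:
        warnings.warn(
            f"consensus {motif_name} (length {k}) longer than search window",
            ScanWarning,
        )
        return []
    candidates = []
    for s in range(lo, hi - k + 1):
        mm = _hamming(seq[s:s + k], consensus)
        if mm <= max_mismatch:
            candidates.append((s, s + k, mm))
    return [MotifHit(motif_name, (s, e), mm) for s, e, mm in _select_fuzzy(candidates)]


def find_polyq(record: SequenceRecord, min_length: int = 6,
               min_fraction: float = 0.8) -> list[MotifHit]:
    """Find glutamine-rich tracts.

    A hit is a maximal interval of length ≥ ``min_length`` whose Q fraction
    is ≥ ``min_fraction`` and whose first and last residues are Q.  For each
    leftmost eligible start the longest valid extension is taken; hits do
    not overlap.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    _check_alphabet(record)
    seq = record.residues
    n = len(seq)
    hits: list[MotifHit] = []
    cursor = 0
    i = 0
    while i < n:
        if seq[i] != "Q" or i < cursor:
            i += 1
            continue
        # longest j >= i+min_length-1 with seq[j]=='Q' and Q-fraction >= min_fraction
        best_j = -1
        q_count = 0
        for j in range(i, n):
            if seq[j] == "Q":
                q_count += 1
                length = j - i + 1
                if length >= min_length and q_count / length >= min_fraction:
                    best_j = j
        if best_j >= 0:
            q_in = seq[i:best_j + 1].count("Q")
            hits.append(MotifHit("POLYQ", (i, best_j + 1), 0))
            cursor = best_j + 1
            i = best_j + 1
        else:
            i += 1
    return hits


def _zf_candidates(seq: str, params: ScanParams) -> list[tuple[int, int, str, tuple]]:
    """All spans matching either finger pattern, as (start, end, class, coords)."""
    out = []
    a_lo, a_hi = params.zf_gap1
    b_lo, b_hi = params.zf_gap2
    c_lo, c_hi = params.zf_gap3
    n = len(seq)
    for p1 in range(n):
        if seq[p1] != "C":
            continue
        for a in range(a_lo, a_hi + 1):
            p2 = p1 + 1 + a
            if p2 >= n or seq[p2] != "C":
                continue
            for b in range(b_lo, b_hi + 1):
                p3 = p2 + 1 + b
                if p3 >= n or seq[p3] != "H":
                    continue
                for c in range(c_lo, c_hi + 1):
                    p4 = p3 + 1 + c
                    if p4 >= n:
                        continue
                    if seq[p4] == "H":
                        out.append((p1, p4 + 1, "C2H2", (p1, p2, p3, p4)))
                    elif seq[p4] == "C":
                        out.append((p1, p4 + 1, "C2HC", (p1, p2, p3, p4)))
    return out


def find_zinc_fingers(record: SequenceRecord,
                      params: ScanParams = ScanParams()) -> list[ZincFingerHit]:
    """Detect C2H2 and C2HC zinc fingers.

    Candidate spans matching ``C-x(1,5)-C-x(10,14)-H-x(3,6)-[HC]`` are
    resolved to a non-overlapping set: scanning left to right, the leftmost
    candidate wins, the longest on equal starts, and C2H2 beats C2HC on an
    identical span.  ``contains_salbox`` is set when an exact Sal-box lies
    inside the finger span.
    """
    _check_alphabet(record)
    seq = record.residues
    cands = _zf_candidates(seq, params)
    # order: start asc, length desc, C2H2 before C2HC
    cands.sort(key=lambda c: (c[0], -(c[1] - c[0]), 0 if c[2] == "C2H2" else 1))
    chosen = []
    cursor = 0
    for s, e, cls, coords in cands:
        if s >= cursor:
            chosen.append((s, e, cls, coords))
            cursor = e
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ScanWarning)
        exact_boxes = find_salbox(record, max_mismatch=0,
                                  consensus=params.salbox_consensus)
    hits = []
    for s, e, cls, coords in chosen:
        has_box = any(b.start >= s and b.end <= e for b in exact_boxes)
        hits.append(ZincFingerHit(cls, (s, e), coords, has_box))
    return hits


def pair_fingers(fingers: Sequence[ZincFingerHit], salboxes: Sequence[MotifHit],
                 max_link: int = 12) -> list[PairedDomain]:
    """Assemble H/C-linked finger pairs, greedily left to right.

    Each Sal-box-bearing C2H2 finger becomes the C-finger of a pair; the
    nearest preceding unpaired C2H2 finger whose spacer to it is at most
    ``max_link`` residues becomes the N-finger.  With no such neighbour the
    pair is degenerate (``lost_N``) — consistent with the observation that
    when one finger of a pair is lost it is the N-terminal one.  ``lost_C``
    is never assigned here; that judgement needs architecture context.
    """
    fingers = sorted(fingers, key=lambda f: f.span)
    paired: set[int] = set()
    pairs: list[PairedDomain] = []
    for i, f in enumerate(fingers):
        if f.zf_class != "C2H2" or not f.contains_salbox or i in paired:
            continue
        box = next((b for b in salboxes if b.start >= f.start and b.end <= f.end), None)
        if box is None:
            box = MotifHit("SALBOX", (f.start, f.start + 8), 0)
        n_finger = None
        n_idx = None
        for j in range(i - 1, -1, -1):
            g = fingers[j]
            if j in paired or g.zf_class != "C2H2" or g.contains_salbox:
                continue
            if g.end <= f.start and f.start - g.end <= max_link:
                n_finger = g
                n_idx = j
            break
        if n_finger is not None:
            paired.add(n_idx)
            paired.add(i)
            pairs.append(PairedDomain(f, box, n_finger, "none"))
        else:
            paired.add(i)
            pairs.append(PairedDomain(f, box, None, "lost_N"))
    # soundness check: Sal-box inside the C-finger for every complete pair
    for p in pairs:
        assert p.salbox.start >= p.c_finger.start and p.salbox.end <= p.c_finger.end
    return pairs


@dataclass
class ScanResult:
    """All grammar features of one record, as produced by :func:`scan_record`."""

    record: SequenceRecord
    fingers: list[ZincFingerHit] = field(default_factory=list)
    pairs: list[PairedDomain] = field(default_factory=list)
    salboxes: list[MotifHit] = field(default_factory=list)
    polyq: list[MotifHit] = field(default_factory=list)
    pre_zf3: list[MotifHit] = field(default_factory=list)
    nurd: list[MotifHit] = field(default_factory=list)

    def all_hits(self) -> list[tuple]:
        """Flat hit table rows: (feature, class, start, end, mismatches)."""
        rows = []
        for f in self.fingers:
            rows.append(("ZINC_FINGER", f.zf_class, f.start, f.end, 0))
        for m in self.salboxes:
            rows.append(("SALBOX", "", m.start, m.end, m.mismatches))
        for m in self.polyq:
            rows.append(("POLYQ", "", m.start, m.end, m.mismatches))
        for m in self.pre_zf3:
            rows.append(("PRE_ZF3_CONSENSUS", "", m.start, m.end, m.mismatches))
        for m in self.nurd:
            rows.append(("NURD", "", m.start, m.end, m.mismatches))
        for p in self.pairs:
            rows.append(("PAIR", p.degenerate_side, p.start, p.end, 0))
        rows.sort(key=lambda r: (r[2], r[3], r[0]))
        return rows


def scan_record(record: SequenceRecord, params: ScanParams = ScanParams()) -> ScanResult:
    """Run every scanner on one record and assemble finger pairs.

    Short sequences legitimately lack room for some motifs; the per-motif
    too-short warnings are suppressed here (an absent motif is simply absent).
    """
    record.validate()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ScanWarning)
        fingers = find_zinc_fingers(record, params)
        salboxes = find_salbox(record, params.salbox_max_mismatch,
                               params.salbox_consensus)
        exact = [b for b in salboxes if b.mismatches <= params.salbox_member_mismatch]
        pairs = pair_fingers(fingers, exact, params.max_link)
        polyq = find_polyq(record, params.polyq_min_length, params.polyq_min_fraction)
        pre_zf3 = find_motif(record, params.pre_zf3_consensus,
                             params.pre_zf3_max_mismatch,
                             motif_name="PRE_ZF3_CONSENSUS")
        nurd = find_motif(record, params.nurd_consensus, params.nurd_max_mismatch,
                          search_window=(0, min(params.nurd_window,
                                                len(record.residues))),
                          motif_name="NURD")
    return ScanResult(record, fingers, pairs, salboxes, polyq, pre_zf3, nurd)
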