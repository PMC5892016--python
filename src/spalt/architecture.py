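"""Homology-class labelling of scanned Sall features.

The canonical bilaterian Sall architecture, N → C, is::

    NURD - ZF1 - POLYQ - ZF2 - ZF3 - ZF3A - ZF4 - ZF5 - ZF6

where ZF1 is a single C2HC finger, ZF2–ZF5 are H/C-linked Sal-box pairs,
ZF3A is the single extra finger associated with the ZF3 pair, and ZF6 is
the single Sal-box-free C2H2 finger at the C terminus.  Classification is
positional and anchored on ZF3, which is recognised either by the conserved
consensus stretch immediately N-terminal of it or by its associated finger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .records import SequenceRecord
from .scan import PairedDomain, ScanParams, ScanResult, ZincFingerHit, scan_record

#: Domain classes in canonical N->C order.
DOMAIN_CLASSES = ("NURD", "ZF1", "POLYQ", "ZF2", "ZF3", "ZF3A", "ZF4", "ZF5", "ZF6")
ZF_CLASSES = ("ZF1", "ZF2", "ZF3", "ZF4", "ZF5", "ZF6")


@dataclass(frozen=True)
class DomainAnnotation:
    label: str                       # one of DOMAIN_CLASSES, "ZFX" or "UNASSIGNED"
    span: tuple[int, int]
    evidence: object = None          # underlying hit(s)
    degenerate_side: str = "none"

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]


@dataclass
class DomainArchitecture:
    """Ordered, non-overlapping labelled domains on one sequence."""

    record_id: str
    taxon: str
    annotations: list[DomainAnnotation] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def labels(self) -> list[str]:
        return [a.label for a in self.annotations]

    def get(self, label: str) -> Optional[DomainAnnotation]:
        for a in self.annotations:
            if a.label == label:
                return a
        return None

    def has(self, label: str) -> bool:
        return self.get(label) is not None

    def _check(self) -> None:
        spans = [a.span for a in self.annotations]
        assert spans == sorted(spans), "annotations not sorted by start"
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2, "overlapping annotations"
        unique = [a.label for a in self.annotations if a.label in DOMAIN_CLASSES]
        assert len(unique) == len(set(unique)), "duplicate class label"


def classify_architecture(record: SequenceRecord,
                          scan: Optional[ScanResult] = None,
                          params: ScanParams = ScanParams()) -> DomainArchitecture:
    """Assign homology-class labels to the scanned features of one record.

    Anchored rules, applied in order:

    1. NURD: the N-terminal-window 12-mer motif hit.
    2. ZF1: the first unpaired C2HC finger preceding all Sal-box pairs.
    3. POLYQ: the poly-Q tract between ZF1 (or the start) and the first pair.
    4. ZF3 anchor: the Sal-box pair preceded within ``pre_zf3_window`` by the
       conserved consensus; failing that, the pair followed within
       ``zf3a_window`` by an extra unpaired C2H2 finger (labelled ZF3A).
       With no anchor, pairs are labelled positionally ZF2..ZF5 and the
       architecture is flagged ``ambiguous_no_zf3_anchor``.
    5. Pairs before the anchor → ZF2; after it → ZF4 then ZF5 when two
       remain.  A single trailing pair is labelled ZF5 — mirroring the
       repeated observation that ZF4 is the more commonly lost of the two —
       and flagged ``ambiguous_zf4_zf5``.
    6. ZF6: the last single Sal-box-free C2H2 finger C-terminal to all pairs.
    7. Anything left → ZFX.
    """
    if scan is None:
        scan = scan_record(record, params)
    annots: list[DomainAnnotation] = []
    flags: list[str] = []
    pairs = sorted(scan.pairs, key=lambda p: p.span)
    used_fingers: set[tuple[int, int]] = set()
    for p in pairs:
        used_fingers.add(p.c_finger.span)
        if p.n_finger is not None:
            used_fingers.add(p.n_finger.span)
    free_fingers = [f for f in scan.fingers if f.span not in used_fingers]

    if not (scan.fingers or scan.salboxes or scan.polyq or scan.pre_zf3 or scan.nurd):
        arch = DomainArchitecture(record.id, record.taxon, [], ["no features"])
        return arch

    # 1. NURD
    if scan.nurd:
        annots.append(DomainAnnotation("NURD", scan.nurd[0].span, scan.nurd[0]))

    first_pair_start = pairs[0].start if pairs else len(record.residues)

    # 2. ZF1
    zf1 = None
    for f in free_fingers:
        if f.zf_class == "C2HC" and f.end <= first_pair_start:
            zf1 = f
            break
    if zf1 is not None:
        annots.append(DomainAnnotation("ZF1", zf1.span, zf1))

    # 3. POLYQ between ZF1 (or start) and the first pair
    polyq_lo = zf1.end if zf1 is not None else 0
    for q in scan.polyq:
        if q.start >= polyq_lo and q.end <= first_pair_start:
            annots.append(DomainAnnotation("POLYQ", q.span, q))
            break

    # 4. ZF3 anchor
    anchor_idx = None
    for i, p in enumerate(pairs):
        for m in scan.pre_zf3:
            if m.end <= p.start and p.start - m.end <= params.pre_zf3_window:
                anchor_idx = i
                break
        if anchor_idx is not None:
            break
    zf3a: Optional[ZincFingerHit] = None

    def _associated_finger(p: PairedDomain) -> Optional[ZincFingerHit]:
        nxt = next((q.start for q in pairs if q.start >= p.end), len(record.residues))
        for f in free_fingers:
            if (f.zf_class == "C2H2" and not f.contains_salbox
                    and f.start >= p.end and f.start - p.end <= params.zf3a_window
                    and f.end <= nxt and f is not zf1):
                return f
        return None

    if anchor_idx is None:
        for i, p in enumerate(pairs):
            f = _associated_finger(p)
            if f is not None:
                anchor_idx = i
                zf3a = f
                break
    else:
        zf3a = _associated_finger(pairs[anchor_idx])

    # 5. label the pairs
    pair_labels: dict[int, str] = {}
    if pairs:
        if anchor_idx is None:
            flags.append("ambiguous_no_zf3_anchor")
            order = ["ZF2", "ZF3", "ZF4", "ZF5"]
            for i, p in enumerate(pairs):
                pair_labels[i] = order[i] if i < 4 else "ZFX"
        else:
            pair_labels[anchor_idx] = "ZF3"
            before = list(range(anchor_idx))
            after = list(range(anchor_idx + 1, len(pairs)))
            if before:
                pair_labels[before[-1]] = "ZF2"
                for i in before[:-1]:
                    pair_labels[i] = "ZFX"
                    flags.append("extra_pair_before_zf3")
            if len(after) >= 2:
                pair_labels[after[0]] = "ZF4"
                pair_labels[after[1]] = "ZF5"
                for i in after[2:]:
                    pair_labels[i] = "ZFX"
                    flags.append("extra_pair_after_zf5")
            elif len(after) == 1:
                pair_labels[after[0]] = "ZF5"
                flags.append("ambiguous_zf4_zf5")
    for i, p in enumerate(pairs):
        annots.append(DomainAnnotation(pair_labels[i], p.span, p, p.degenerate_side))
    if zf3a is not None:
        annots.append(DomainAnnotation("ZF3A", zf3a.span, zf3a))

    # 6. ZF6: last single Sal-box-free C2H2 after all pairs
    last_pair_end = pairs[-1].end if pairs else 0
    zf6 = None
    for f in free_fingers:
        if (f.zf_class == "C2H2" and not f.contains_salbox
                and f.start >= last_pair_end and f is not zf3a):
            zf6 = f
    if zf6 is not None:
        annots.append(DomainAnnotation("ZF6", zf6.span, zf6))

    # 7. leftovers
    taken = {a.span for a in annots}
    for f in free_fingers:
        if f.span not in taken:
            annots.append(DomainAnnotation("ZFX", f.span, f))

    # overlap resolution: earlier rules win, the loser is dropped and flagged
    annots.sort(key=lambda a: a.span)
    cleaned: list[DomainAnnotation] = []
    for a in annots:
        if cleaned and a.start < cleaned[-1].end:
            flags.append(f"overlap_dropped:{a.label}")
            continue
        cleaned.append(a)

    arch = DomainArchitecture(record.id, record.taxon, cleaned, flags)
    arch._check()
    return arch


_DEGENERATE_SUFFIX = {"lost_N": "ΔN", "lost_C": "ΔC"}


def architecture_string(arch: DomainArchitecture) -> str:
    """Canonical hyphen-joined rendering, degenerate pairs suffixed ΔN/ΔC."""
    parts = []
    for a in arch.annotations:
        suffix = _DEGENERATE_SUFFIX.get(a.degenerate_side, "")
        parts.append(a.label + suffix)
    return "-".join(parts)


@dataclass
class PresenceMatrix:
    """Taxa × domain-class binary matrix with per-entry provenance.

    ``values`` and ``provenance`` are aligned DataFrames (taxa rows, class
    columns); provenance entries are ``scanned``, ``text_stated`` or
    ``default_present``.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def classes(self) -> list[str]:
        return list(self.values.columns)

    def _check(self) -> None:
        assert set(self.values.values.ravel()) <= {0, 1}, "matrix not binary"
        assert self.values.index.is_unique and self.values.columns.is_unique

    def leaf_states(self, cls: str) -> dict[str, int]:
        return {t: int(v) for t, v in self.values[cls].items()}

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0).astype(int)
        prov = df.copy().astype(object)
        prov[:] = "scanned"
        m = cls(df, prov)
        m._check()
        return m


def presence_matrix(archs: Sequence[DomainArchitecture],
                    classes: Iterable[str] = DOMAIN_CLASSES) -> PresenceMatrix:
    """Binary presence of each domain class per taxon.

    Degenerate (ΔN/ΔC) pairs count as present, matching the convention of
    rendering modified domains as present-but-modified.
    """
    classes = list(classes)
    taxa = [a.taxon for a in archs]
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon among architectures")
    data = {}
    for arch in archs:
        data[arch.taxon] = [1 if arch.has(c) else 0 for c in classes]
    df = pd.DataFrame.from_dict(data, orient="index", columns=classes).astype(int)
    prov = df.copy().astype(object)
    prov[:] = "scanned"
    m = PresenceMatrix(df, prov)
    m._check()
    return m
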