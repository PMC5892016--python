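"""Synthetic Sal-like proteins and families with planted ground truth.

The generator emulates the canonical Sall grammar so that every scanner,
classifier and reconstruction step can be exercised without any external
sequence: planted C2HC/C2H2 zinc fingers, H/C-linked finger pairs whose
C-terminal finger carries the Sal-box ``FTTKGNLK``, a poly-Q tract, a
12-residue N-terminal NuRD-style motif, the conserved pre-ZF3 consensus
``SETSKLQQLVENID``, configurable domain losses along a tree, and
background substitution noise.

Linker residues are drawn uniformly from the 20 amino acids minus
``C``, ``H`` and ``Q``, so the background can neither spell a spurious
zinc finger nor extend a poly-Q tract.  Substitution noise likewise draws
replacements from that restricted set, and zinc-coordinating residues and
Sal-box positions are protected by default, so planted truth stays
well-defined; both protections are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .records import AMINO_ACIDS, SequenceRecord
from .scan import DEFAULT_NURD_CONSENSUS, PRE_ZF3_CONSENSUS
from .trees import Node, Tree

#: Background alphabet for linkers and substitutions (no C/H/Q).
BACKGROUND_LETTERS = "".join(c for c in AMINO_ACIDS if c not in "CHQ")

# Planted building blocks.  Zinc fingers follow C-x(1,5)-C-x(10,14)-H-x(3,6)-[HC];
# coordinating positions within each 21-mer are 0, 3, 16, 20.
ZF1_C2HC = "CPECGKSFSRLENLKTHIRSC"
PAIR_N_FINGER = "CGKCNRSFSDRSNLNRHMKTH"
PAIR_LINK = "GSGSG"
PAIR_C_FINGER = "CPDCGKAFTTKGNLKVHRRTH"   # Sal-box FTTKGNLK at offset 7
SINGLE_C2H2_ZF3A = "CGRCDMSFADNSALSRHMRSH"
SINGLE_C2H2_ZF6 = "CSKCPFVTDSLPLLRAHVRQH"
SINGLE_C2H2_EXTRA = "CNRCGASFADKSTLVRHTKTH"  # SEM-4-style N-terminal orphan
SINGLE_C2HC_EXTRA = "CGECGKDFSMKSALTKHLDSC"  # SEM-4-style C-terminal orphan
POLYQ_TRACT = "Q" * 10

_COORD_OFFSETS = (0, 3, 16, 20)
_SALBOX_OFFSET_IN_C = 7


@dataclass(frozen=True)
class FeaturePlan:
    """One planted feature: label, kind and the residues to plant.

    ``kind`` is one of ``motif``, ``polyq``, ``finger`` (a single zinc
    finger) or ``pair`` (N-finger + H/C link + Sal-box C-finger).
    ``linker_range`` is the inclusive range of background residues placed
    before the feature.
    """

    label: str
    kind: str
    sequence: str
    linker_range: tuple[int, int] = (8, 20)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered feature plan plus noise model for one synthetic protein."""

    features: tuple[FeaturePlan, ...]
    mutation_rate: float = 0.0
    background: str = BACKGROUND_LETTERS
    trailing_linker: tuple[int, int] = (8, 20)
    protect_anchors: bool = True
    seed: int = 0

    def without(self, labels) -> "ArchitectureSpec":
        drop = set(labels)
        return replace(self, features=tuple(f for f in self.features
                                            if f.label not in drop))


def canonical_spec(seed: int = 0, mutation_rate: float = 0.0) -> ArchitectureSpec:
    """The full canonical grammar: NURD-ZF1-POLYQ-ZF2-ZF3-ZF3A-ZF4-ZF5-ZF6.

    The pre-ZF3 consensus is planted close enough to the ZF3 pair to anchor
    it; ZF6 sits far enough past ZF5 that it can never be mistaken for the
    ZF3-associated finger.
    """
    pair = PAIR_N_FINGER + PAIR_LINK + PAIR_C_FINGER
    return ArchitectureSpec(
        features=(
            FeaturePlan("NURD", "motif", DEFAULT_NURD_CONSENSUS, (0, 5)),
            FeaturePlan("ZF1", "finger", ZF1_C2HC, (8, 20)),
            FeaturePlan("POLYQ", "polyq", POLYQ_TRACT, (8, 20)),
            FeaturePlan("ZF2", "pair", pair, (8, 20)),
            FeaturePlan("PRE_ZF3", "motif", PRE_ZF3_CONSENSUS, (8, 20)),
            FeaturePlan("ZF3", "pair", pair, (4, 12)),
            FeaturePlan("ZF3A", "finger", SINGLE_C2H2_ZF3A, (8, 20)),
            FeaturePlan("ZF4", "pair", pair, (8, 20)),
            FeaturePlan("ZF5", "pair", pair, (8, 20)),
            FeaturePlan("ZF6", "finger", SINGLE_C2H2_ZF6, (45, 60)),
        ),
        mutation_rate=mutation_rate,
        seed=seed,
    )


def sem4_like_spec(seed: int = 0) -> ArchitectureSpec:
    """A SEM-4-style architecture: two unique orphan fingers at the termini,
    one consensus-anchored Sal-box pair (ZF3) and one later pair (ZF5)."""
    pair = PAIR_N_FINGER + PAIR_LINK + PAIR_C_FINGER
    return ArchitectureSpec(
        features=(
            FeaturePlan("ZFX_N", "finger", SINGLE_C2H2_EXTRA, (0, 5)),
            FeaturePlan("PRE_ZF3", "motif", PRE_ZF3_CONSENSUS, (45, 60)),
            FeaturePlan("ZF3", "pair", pair, (4, 12)),
            FeaturePlan("ZF5", "pair", pair, (45, 60)),
            FeaturePlan("ZFX_C", "finger", SINGLE_C2HC_EXTRA, (45, 60)),
        ),
        seed=seed,
    )


@dataclass
class PlantedProtein:
    """A generated record plus its planted annotation truth."""

    record: SequenceRecord
    spans: dict[str, tuple[int, int]]
    protected: frozenset[int]
    spec: ArchitectureSpec


def _protected_offsets(plan: FeaturePlan) -> set[int]:
    if plan.kind == "finger":
        return set(_COORD_OFFSETS)
    if plan.kind == "pair":
        off = set(_COORD_OFFSETS)
        c_start = len(PAIR_N_FINGER) + len(PAIR_LINK)
        off |= {c_start + o for o in _COORD_OFFSETS}
        off |= set(range(c_start + _SALBOX_OFFSET_IN_C,
                         c_start + _SALBOX_OFFSET_IN_C + 8))
        return off
    return set()


def make_protein(spec: ArchitectureSpec,
                 rng: Optional[np.random.Generator] = None) -> PlantedProtein:
    """Realise a spec into a sequence; deterministic given the spec seed.

    Point substitutions are applied at ``mutation_rate`` to every position
    except (by default) zinc-coordinating and Sal-box positions; for a fixed
    seed the set of mutated positions grows monotonically with the rate, so
    recovery can only degrade as noise rises.
    """
    if not (0 <= spec.mutation_rate < 1):
        raise ValueError("mutation_rate must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    bg = list(spec.background)
    chars: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    protected: set[int] = set()

    def linker(lo: int, hi: int) -> None:
        if lo > hi or lo < 0:
            raise ValueError(f"infeasible linker range ({lo}, {hi})")
        k = int(rng.integers(lo, hi + 1))
        chars.extend(rng.choice(bg, size=k).tolist() if k else [])

    for plan in spec.features:
        linker(*plan.linker_range)
        start = len(chars)
        chars.extend(plan.sequence)
        spans[plan.label] = (start, len(chars))
        if spec.protect_anchors:
            protected |= {start + o for o in _protected_offsets(plan)}
            if plan.kind in ("motif", "polyq"):
                # keep consensus motifs and the Q tract intact as well:
                # their identity is the planted truth
                protected |= set(range(start, len(chars)))
    linker(*spec.trailing_linker)

    # coupled mutation draws: one uniform and one replacement per position
    u = rng.random(len(chars))
    repl = rng.choice(bg, size=len(chars))
    for i in range(len(chars)):
        if u[i] < spec.mutation_rate and i not in protected:
            chars[i] = str(repl[i])
    record = SequenceRecord(f"synthetic_{spec.seed}", f"synthetic_{spec.seed}",
                            "".join(chars)).validate()
    return PlantedProtein(record, spans, frozenset(protected), spec)


# ---- family simulation -------------------------------------------------

@dataclass
class FamilyTruth:
    """Ground truth of a simulated family."""

    tree: Tree
    root_spec: ArchitectureSpec
    loss_plan: dict[str, tuple[str, ...]]
    leaf_records: list[SequenceRecord] = field(default_factory=list)
    leaf_spans: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    leaf_features: dict[str, frozenset[str]] = field(default_factory=dict)


@dataclass
class _Segment:
    label: Optional[str]
    chars: list[str]
    protected: list[bool]


def evolve_family(tree: Tree, root_spec: ArchitectureSpec,
                  loss_plan: Mapping[str, Sequence[str]],
                  substitution_rate: float = 0.0,
                  seed: int = 0) -> FamilyTruth:
    """Evolve one planted protein down a tree with per-branch domain losses.

    ``loss_plan`` maps a node label (the child end of a branch) to the
    feature labels excised on that branch; a label lost upstream cannot be
    lost again.  Substitutions are applied per branch at
    ``substitution_rate`` × branch length (edge count 1 when lengths are
    unset), outside protected positions, and therefore accumulate with path
    length.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    bg = list(root_spec.background)
    known = {f.label for f in root_spec.features}
    node_names = set()
    for n in tree.preorder():
        if n.label:
            node_names.add(n.label)
    for name, labels in loss_plan.items():
        if name not in node_names:
            raise ValueError(f"loss_plan branch {name!r} not a labelled node")
        unknown = set(labels) - known
        if unknown:
            raise ValueError(f"loss_plan features not in root spec: {sorted(unknown)}")

    # realise the root once, then inherit segments down the tree
    root_segments: list[_Segment] = []

    def linker(lo: int, hi: int) -> None:
        k = int(rng.integers(lo, hi + 1))
        root_segments.append(
            _Segment(None, rng.choice(bg, size=k).tolist(), [False] * k))

    for plan in root_spec.features:
        linker(*plan.linker_range)
        prot = _protected_offsets(plan)
        if plan.kind in ("motif", "polyq"):
            prot = set(range(len(plan.sequence)))
        mask = [i in prot for i in range(len(plan.sequence))]
        if not root_spec.protect_anchors:
            mask = [False] * len(plan.sequence)
        root_segments.append(_Segment(plan.label, list(plan.sequence), mask))
    linker(*root_spec.trailing_linker)

    truth = FamilyTruth(tree, root_spec, {k: tuple(v) for k, v in loss_plan.items()})

    def mutate(segments: list[_Segment], rate: float) -> None:
        for seg in segments:
            n = len(seg.chars)
            if n == 0:
                continue
            u = rng.random(n)
            repl = rng.choice(bg, size=n)
            for i in range(n):
                if u[i] < rate and not seg.protected[i]:
                    seg.chars[i] = str(repl[i])

    def copy_segments(segments: list[_Segment]) -> list[_Segment]:
        return [_Segment(s.label, list(s.chars), list(s.protected))
                for s in segments]

    def descend(node: Node, segments: list[_Segment]) -> None:
        for child in node.children:
            segs = copy_segments(segments)
            name = child.label
            if name and name in loss_plan:
                have = {s.label for s in segs if s.label}
                gone = set(loss_plan[name]) - have
                if gone:
                    raise ValueError(
                        f"loss of {sorted(gone)} on branch {name!r}: "
                        "already lost upstream")
                segs = [s for s in segs
                        if s.label is None or s.label not in loss_plan[name]]
            edge = child.length if child.length is not None else 1.0
            if substitution_rate > 0:
                mutate(segs, min(0.999, substitution_rate * edge))
            if child.is_leaf:
                chars: list[str] = []
                spans: dict[str, tuple[int, int]] = {}
                for s in segs:
                    start = len(chars)
                    chars.extend(s.chars)
                    if s.label:
                        spans[s.label] = (start, len(chars))
                rec = SequenceRecord(child.label, child.label,
                                     "".join(chars)).validate()
                truth.leaf_records.append(rec)
                truth.leaf_spans[child.label] = spans
                truth.leaf_features[child.label] = frozenset(spans)
            else:
                descend(child, segs)

    descend(tree.root, root_segments)
    return truth


# ---- orthology test data ----------------------------------------------

def two_family_dataset(seed: int = 0, n_sall_refs: int = 3,
                       n_candidates: int = 3, n_other: int = 4,
                       length: int = 70, within: float = 0.04,
                       between: float = 0.6):
    """Two well-separated clusters for orthology calling.

    One cluster holds reference Sall sequences plus the planted candidates,
    the other a diverged Sal-box family (labelled ``schnurri``).  Within-
    cluster divergence is small, between-cluster divergence large, so the
    Sall clade is recovered with full bootstrap support.

    Returns ``(records, reference_labels, candidate_ids)``.
    """
    rng = np.random.default_rng(seed)
    aa = list(AMINO_ACIDS)

    def mutate(s: str, rate: float) -> str:
        out = list(s)
        for i in range(len(out)):
            if rng.random() < rate:
                out[i] = str(rng.choice(aa))
        return "".join(out)

    sall_base = "".join(rng.choice(aa, size=length))
    other_base = mutate(sall_base, between)
    records = []
    reference_labels: dict[str, str] = {}
    candidate_ids = []
    for i in range(n_sall_refs):
        rid = f"Sall_ref{i}"
        records.append(SequenceRecord(rid, rid, mutate(sall_base, within)))
        reference_labels[rid] = "sall"
    for i in range(n_candidates):
        rid = f"candidate{i}"
        records.append(SequenceRecord(rid, rid, mutate(sall_base, within)))
        candidate_ids.append(rid)
    for i in range(n_other):
        rid = f"Schnurri_ref{i}"
        records.append(SequenceRecord(rid, rid, mutate(other_base, within)))
        reference_labels[rid] = "schnurri"
    return records, reference_labels, candidate_ids
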