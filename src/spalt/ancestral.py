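"""Ancestral presence/absence reconstruction and gain/loss mapping.

Two parsimony reconstructions over a rooted species tree and a binary
taxa × domain-class matrix:

* **Fitch** (unordered, minimum change; Hartigan's generalisation, so
  multifurcations are handled exactly).  Ambiguous internal states are kept
  as sets; for event mapping a single most-parsimonious resolution is chosen
  with a documented tie rule — prefer presence at the root, then prefer the
  parent's state — mirroring the plesiomorphy-then-loss reading of domain
  evolution.
* **Dollo** (single gain, any number of losses).  The gain node is the last
  common ancestor of all taxa carrying the domain; losses sit on the highest
  branches consistent with the tip states, which minimises the loss count
  subject to the single-gain constraint.

Events are reported per branch, identified by the child node; the branch
into the root carries root-state gains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .architecture import PresenceMatrix, ZF_CLASSES
from .trees import Node, Tree


class ReconstructionWarning(UserWarning):
    pass


@dataclass
class Reconstruction:
    """Per-node states and per-branch events for one or more characters."""

    tree: Tree
    method: str                                   # "fitch" | "dollo"
    characters: list[str]
    node_ids: dict[int, str] = field(default_factory=dict)   # id(node) -> name
    states: dict[str, dict[str, int]] = field(default_factory=dict)
    state_sets: dict[str, dict[str, frozenset[int]]] = field(default_factory=dict)
    events: list[tuple[int, str, str, str]] = field(default_factory=list)
    #   (preorder branch index, branch name = child node name, character, gain|loss)
    total_changes: dict[str, int] = field(default_factory=dict)

    def node_state(self, node_name: str, character: str) -> int:
        return self.states[character][node_name]

    def events_frame(self) -> pd.DataFrame:
        rows = sorted(self.events)
        return pd.DataFrame(
            [(b, ch, ev) for _, b, ch, ev in rows],
            columns=["branch", "character", "event"],
        )


def _node_names(tree: Tree) -> dict[int, str]:
    """Stable node naming: existing labels kept, anonymous internals named
    by preorder index (``node<i>``)."""
    names: dict[int, str] = {}
    used: set[str] = set()
    for i, n in enumerate(tree.preorder()):
        name = n.label if n.label else f"node{i}"
        if name in used:
            name = f"{name}.{i}"
        used.add(name)
        names[id(n)] = name
    return names


def _check_taxa(tree: Tree, matrix: PresenceMatrix) -> None:
    leaves = set(tree.leaf_labels())
    taxa = set(matrix.taxa)
    if leaves != taxa:
        raise ValueError(
            f"tree/matrix mismatch: only in tree {sorted(leaves - taxa)}, "
            f"only in matrix {sorted(taxa - leaves)}"
        )


def _map_events(tree: Tree, names: dict[int, str],
                states: dict[str, int], character: str) -> list[tuple[int, str, str, str]]:
    """State flips along branches; the root branch carries a gain when the
    root state is 1 (the character must have arisen somewhere below nothing)."""
    events = []
    preorder = list(tree.preorder())
    index = {id(n): i for i, n in enumerate(preorder)}
    root_name = names[id(tree.root)]
    if states[root_name] == 1:
        events.append((0, root_name, character, "gain"))
    for n in preorder:
        for c in n.children:
            s_p = states[names[id(n)]]
            s_c = states[names[id(c)]]
            if s_c != s_p:
                events.append((index[id(c)], names[id(c)], character,
                               "gain" if s_c == 1 else "loss"))
    return events


def fitch(tree: Tree, matrix: PresenceMatrix) -> Reconstruction:
    """Minimum-change (Fitch/Hartigan) reconstruction of every character."""
    _check_taxa(tree, matrix)
    names = _node_names(tree)
    rec = Reconstruction(tree, "fitch", list(matrix.classes), names)
    post = list(tree.postorder())
    pre = list(tree.preorder())
    for ch in matrix.classes:
        leaf_states = matrix.leaf_states(ch)
        B: dict[int, frozenset[int]] = {}
        T: dict[int, frozenset[int]] = {}
        changes = 0
        for n in post:
            if n.is_leaf:
                B[id(n)] = frozenset([leaf_states[n.label]])
                T[id(n)] = frozenset()
            else:
                count = {0: 0, 1: 0}
                for c in n.children:
                    for s in B[id(c)]:
                        count[s] += 1
                k = max(count.values())
                B[id(n)] = frozenset(s for s in (0, 1) if count[s] == k)
                T[id(n)] = frozenset(s for s in (0, 1) if count[s] == k - 1)
                changes += len(n.children) - k
        # top-down resolution: root prefers presence; children keep the
        # parent state whenever it is optimal or co-optimal (B or T set)
        resolved: dict[str, int] = {}
        for n in pre:
            name = names[id(n)]
            if n is tree.root:
                resolved[name] = 1 if 1 in B[id(n)] else 0
            else:
                p_state = resolved[names[id(n.parent)]]
                if p_state in B[id(n)] or p_state in T[id(n)]:
                    resolved[name] = p_state
                else:
                    resolved[name] = 1 if 1 in B[id(n)] else 0
        rec.states[ch] = resolved
        rec.state_sets[ch] = {names[k]: v for k, v in B.items()}
        rec.total_changes[ch] = changes
        rec.events.extend(_map_events(tree, names, resolved, ch))
    return rec


def dollo(tree: Tree, matrix: PresenceMatrix) -> Reconstruction:
    """Single-gain / multiple-loss reconstruction of every character."""
    _check_taxa(tree, matrix)
    names = _node_names(tree)
    rec = Reconstruction(tree, "dollo", list(matrix.classes), names)
    pre = list(tree.preorder())
    index = {id(n): i for i, n in enumerate(pre)}
    for ch in matrix.classes:
        leaf_states = matrix.leaf_states(ch)
        present = [t for t, v in leaf_states.items() if v == 1]
        states = {names[id(n)]: 0 for n in pre}
        events: list[tuple[int, str, str, str]] = []
        if not present:
            warnings.warn(f"character {ch!r} absent from every leaf; no gain placed",
                          ReconstructionWarning)
            rec.states[ch] = states
            rec.state_sets[ch] = {k: frozenset([v]) for k, v in states.items()}
            rec.total_changes[ch] = 0
            continue
        gain_node = tree.mrca(present) if len(present) > 1 else tree.find(present[0])
        # below the gain node: present iff the subtree retains a carrier
        def fill(n: Node, inside: bool) -> None:
            if inside:
                if n.is_leaf:
                    states[names[id(n)]] = leaf_states[n.label]
                else:
                    has_carrier = any(leaf_states[l] for l in tree.leaf_set(n))
                    states[names[id(n)]] = 1 if has_carrier else 0
            for c in n.children:
                fill(c, inside or c is gain_node)
        fill(tree.root, tree.root is gain_node)
        events.append((index[id(gain_node)], names[id(gain_node)], ch, "gain"))
        losses = 0
        for n in pre:
            for c in n.children:
                if states[names[id(n)]] == 1 and states[names[id(c)]] == 0:
                    events.append((index[id(c)], names[id(c)], ch, "loss"))
                    losses += 1
        rec.states[ch] = states
        rec.state_sets[ch] = {k: frozenset([v]) for k, v in states.items()}
        rec.total_changes[ch] = 1 + losses
        rec.events.extend(events)
    return rec


def count_node_domains(rec: Reconstruction, node_name: str,
                       classes=ZF_CLASSES) -> int:
    """Number of zinc-finger domain classes (ZF1..ZF6 by default; ZF3A and
    the non-finger NURD/POLYQ characters excluded) present at a node."""
    available = [c for c in classes if c in rec.states]
    return sum(rec.states[c][node_name] for c in available)


def branch_events(rec: Reconstruction) -> pd.DataFrame:
    """Per-branch gain/loss table, sorted by preorder branch index then
    character; branches are named by their child node."""
    return rec.events_frame()
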