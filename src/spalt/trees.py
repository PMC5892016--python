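"""Rooted phylogeny container with Newick I/O.

A small rooted-tree structure shared by the distance-tree builder and the
ancestral-state machinery.  Newick text is parsed through dendropy (so the
full dialect — labels, lengths, comments — is honoured) and converted into
this light representation; writing goes the same way in reverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy


class NewickError(ValueError):
    """Malformed Newick input."""


@dataclass
class Node:
    label: Optional[str] = None
    length: Optional[float] = None
    support: Optional[float] = None
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Rooted tree; leaf labels unique, internal nodes ≥ 2 children."""

    def __init__(self, root: Node):
        self.root = root

    # ---- traversal -----------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def find(self, label: str) -> Optional[Node]:
        for n in self.preorder():
            if n.label == label:
                return n
        return None

    def leaf_set(self, node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.label])
        out = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.add(n.label)
            else:
                stack.extend(n.children)
        return frozenset(out)

    def mrca(self, labels) -> Node:
        """Last common ancestor of the given leaf labels."""
        want = set(labels)
        missing = want - set(self.leaf_labels())
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        node = self.root
        while True:
            covering = [c for c in node.children if want <= self.leaf_set(c)]
            if len(covering) == 1:
                node = covering[0]
            else:
                return node

    def validate(self) -> "Tree":
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickError(f"duplicate leaf labels: {dup}")
        if any(l is None for l in labels):
            raise NewickError("unlabelled leaf")
        for n in self.preorder():
            if not n.is_leaf and len(n.children) < 2:
                raise NewickError("internal node with a single child")
        return self

    def copy(self) -> "Tree":
        def _cp(n: Node) -> Node:
            m = Node(n.label, n.length, n.support)
            for c in n.children:
                m.add(_cp(c))
            return m
        return Tree(_cp(self.root))

    # ---- bipartitions --------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Unrooted bipartitions, each canonicalised as the side NOT
        containing the lexicographically smallest taxon."""
        taxa = frozenset(self.leaf_labels())
        ref = min(taxa)
        out = set()
        for n in self.preorder():
            if n is self.root or n.is_leaf:
                continue
            side = self.leaf_set(n)
            if ref in side:
                side = taxa - side
            if 1 < len(side) < len(taxa) - 1:  # non-trivial splits only
                out.add(side)
        return out


# ---- Newick I/O --------------------------------------------------------

def _from_dendropy(dnode: dendropy.Node) -> Node:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    else:
        label = dnode.label
    n = Node(label=label, length=dnode.edge.length)
    for c in dnode.child_nodes():
        n.add(_from_dendropy(c))
    return n


def parse_newick(text: str) -> Tree:
    """Parse one Newick tree; errors report what went wrong and where."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed Newick: {exc}") from exc
    tree = Tree(_from_dendropy(dtree.seed_node))
    return tree.validate()


def _to_newick(node: Node, with_support: bool) -> str:
    if node.is_leaf:
        s = node.label or ""
    else:
        inner = ",".join(_to_newick(c, with_support) for c in node.children)
        label = node.label or ""
        if with_support and node.support is not None:
            label = f"{node.support:g}"
        s = f"({inner}){label}"
    if node.length is not None:
        s += f":{node.length:g}"
    return s


def write_newick(tree: Tree, with_support: bool = False) -> str:
    """Serialise to Newick; ``with_support`` writes supports as internal
    node labels (the common comparative convention)."""
    return _to_newick(tree.root, with_support) + ";"


# ---- simple random trees (testing / simulation scaffolding) ------------

def random_binary_tree(labels: list[str], rng) -> Tree:
    """Uniform-ish random rooted binary tree over the given leaf labels,
    built by sequential random attachment; branch lengths unset."""
    if len(labels) < 2:
        raise ValueError("need at least two leaves")
    nodes = [Node(label=l) for l in labels]
    order = list(range(len(nodes)))
    rng.shuffle(order)
    lineages = [nodes[i] for i in order]
    while len(lineages) > 1:
        i = int(rng.integers(0, len(lineages)))
        a = lineages.pop(i)
        j = int(rng.integers(0, len(lineages)))
        b = lineages.pop(j)
        p = Node()
        p.add(a)
        p.add(b)
        lineages.append(p)
    return Tree(lineages[0]).validate()
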