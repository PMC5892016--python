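"""Domain-restricted phylogenetics and orthology assignment.

The classification workflow mirrors the two-stage analysis used for
Sal-box proteins: (1) a tree over the ZF3+ZF4 region — the only two
zinc-finger domains shared by every Sal-box protein (Sall, Schnurri,
PRDII-BF1, HIVEP1) — sorts candidates into the Sall family versus the
other Sal-box families; (2) a Sall-only tree over ZF2+ZF3+ZF5 refines
relationships.  Trees are neighbor-joining on corrected distances with
nonparametric bootstrap support; a candidate is called an ortholog when it
falls in a clade with support above 0.95 together with references of known
identity — the same decision threshold as the original Bayesian analysis,
realised here with bootstrap proportions instead of posterior
probabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from skbio import DistanceMatrix

from .align import Alignment, GAP, load_score_table, progressive_align, trim_alignment
from .architecture import DomainArchitecture
from .records import SequenceRecord
from .trees import Node, Tree

#: Domain sets used by the two analysis stages.
SALBOX_SUPERFAMILY_DOMAINS = ("ZF3", "ZF4")
SALL_FAMILY_DOMAINS = ("ZF2", "ZF3", "ZF5")

REFERENCE_FAMILIES = ("sall", "schnurri", "prdii_bf1", "hivep1")


class DomainExtractionError(ValueError):
    pass


class ExtractionWarning(UserWarning):
    pass


def extract_domains(record: SequenceRecord, arch: DomainArchitecture,
                    labels: Sequence[str], strict: bool = True) -> str:
    """Concatenate the spans of the requested domain labels, N→C.

    With ``strict`` any missing label raises; otherwise missing labels are
    skipped with an :class:`ExtractionWarning`.  An empty extraction is
    always an error.
    """
    spans = []
    missing = []
    for lab in labels:
        ann = arch.get(lab)
        if ann is None:
            missing.append(lab)
        else:
            spans.append(ann.span)
    if missing and strict:
        raise DomainExtractionError(
            f"record {record.id!r}: missing domains {missing}")
    if missing:
        warnings.warn(f"record {record.id!r}: skipping missing domains {missing}",
                      ExtractionWarning)
    if not spans:
        if not labels:
            return ""
        raise DomainExtractionError(
            f"record {record.id!r}: none of {list(labels)} present")
    spans.sort()
    return "".join(record.residues[s:e] for s, e in spans)


# ---- distances ---------------------------------------------------------

def distance_matrix(msa: Alignment, model: str = "poisson",
                    alpha: float = 1.0, max_distance: float = 10.0) -> DistanceMatrix:
    """Pairwise distances from an alignment.

    ``p``: mismatch proportion over mutually ungapped columns;
    ``poisson``: ``d = -ln(1 - p)``;
    ``gamma``: ``d = alpha * ((1 - p)^(-1/alpha) - 1)`` — the
    rate-variation-corrected distance standing in for a full ML model.
    Saturated pairs (p = 1) are capped at ``max_distance`` with a warning.
    """
    if model not in ("p", "poisson", "gamma"):
        raise ValueError(f"unknown model {model!r}")
    ids = msa.ids
    if len(ids) < 2:
        raise ValueError("need at least 2 rows")
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r1, r2 = msa.rows[ids[i]], msa.rows[ids[j]]
            pairs = [(x, y) for x, y in zip(r1, r2) if x != GAP and y != GAP]
            if not pairs:
                raise ValueError(f"rows {ids[i]!r}/{ids[j]!r} share no ungapped column")
            p = sum(1 for x, y in pairs if x != y) / len(pairs)
            if model == "p":
                d = p
            elif model == "poisson":
                if p >= 1.0:
                    warnings.warn("saturated pair; distance capped", UserWarning)
                    d = max_distance
                else:
                    d = -math.log(1.0 - p)
            else:
                if p >= 1.0:
                    warnings.warn("saturated pair; distance capped", UserWarning)
                    d = max_distance
                else:
                    d = alpha * ((1.0 - p) ** (-1.0 / alpha) - 1.0)
            D[i, j] = D[j, i] = min(d, max_distance)
    return DistanceMatrix(D, ids)


# ---- neighbor joining --------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> Tree:
    """Standard neighbor joining (Saitou–Nei, Studier–Keppler Q).

    Returns an unrooted tree represented with a trifurcating root; negative
    branch-length estimates are clamped to zero.  Ties in the Q criterion
    resolve to the first (lowest-index) pair, so the result is deterministic
    for a given label order.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = np.array(dm.data, dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix not symmetric")
    nodes: list[Node] = [Node(label=l) for l in labels]
    active = list(range(len(labels)))
    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        best_q = math.inf
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * sub[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        gi, gj = active[i], active[j]
        u = Node()
        a, b = nodes[gi], nodes[gj]
        a.length = max(0.0, li)
        b.length = max(0.0, lj)
        u.add(a)
        u.add(b)
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0] + 1)
        for k_local, gk in enumerate(active):
            if gk in (gi, gj):
                continue
            new_row[gk] = 0.5 * (D[gi, gk] + D[gj, gk] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(u)
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]
    # final three lineages joined at the (trifurcating) root
    ga, gb, gc = active
    dab, dac, dbc = D[ga, gb], D[ga, gc], D[gb, gc]
    root = Node()
    for g, l in ((ga, 0.5 * (dab + dac - dbc)),
                 (gb, 0.5 * (dab + dbc - dac)),
                 (gc, 0.5 * (dac + dbc - dab))):
        nodes[g].length = max(0.0, l)
        root.add(nodes[g])
    return Tree(root).validate()


# ---- bootstrap ---------------------------------------------------------

def _resample(msa: Alignment, rng: np.random.Generator) -> Alignment:
    cols = rng.integers(0, msa.length, size=msa.length)
    return Alignment({rid: "".join(row[c] for c in cols)
                      for rid, row in msa.rows.items()})


def bootstrap_support(seqs: Sequence[SequenceRecord], n_replicates: int = 200,
                      seed: int = 0, model: str = "poisson", alpha: float = 1.0,
                      table: Optional[dict] = None,
                      gap_open: float = -10.0, gap_extend: float = -1.0,
                      max_gap_fraction: float = 0.5,
                      msa: Optional[Alignment] = None) -> Tree:
    """NJ tree with nonparametric bootstrap support.

    The sequences are aligned once (progressively), gap-heavy columns are
    trimmed, and alignment columns are resampled with replacement per
    replicate; each internal branch of the full-data tree gets as support
    the fraction of replicate trees containing its bipartition.
    Deterministic for a given seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if table is None:
        table = load_score_table()
    if msa is None:
        msa = progressive_align(seqs, table, gap_open, gap_extend)
        msa = trim_alignment(msa, max_gap_fraction)
    tree = nj_tree(distance_matrix(msa, model, alpha))
    target = {}
    taxa = frozenset(tree.leaf_labels())
    for node in tree.preorder():
        if node is tree.root or node.is_leaf:
            continue
        side = tree.leaf_set(node)
        if min(taxa) in side:
            side = taxa - side
        target[id(node)] = side
    counts = {k: 0 for k in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        rep = _resample(msa, rng)
        rep_tree = nj_tree(distance_matrix(rep, model, alpha))
        rep_bips = rep_tree.bipartitions()
        for k, side in target.items():
            if side in rep_bips:
                counts[k] += 1
    for node in tree.preorder():
        if id(node) in counts:
            node.support = counts[id(node)] / n_replicates
    return tree


# ---- rooting -----------------------------------------------------------

def _collapse_unary(node: Node) -> None:
    for c in list(node.children):
        _collapse_unary(c)
    if len(node.children) == 1 and node.parent is not None:
        child = node.children[0]
        parent = node.parent
        idx = parent.children.index(node)
        child.parent = parent
        if child.length is not None and node.length is not None:
            child.length += node.length
        child.support = child.support if child.support is not None else node.support
        parent.children[idx] = child


def root_at_leaf_edge(tree: Tree, leaf_label: str) -> Tree:
    """Reroot on the pendant edge of the given leaf (outgroup rooting).

    Supports are re-assigned from the unrooted bipartition they describe, so
    they survive the rerooting.
    """
    tree = tree.copy()
    taxa = frozenset(tree.leaf_labels())
    ref = min(taxa)
    support_map = {}
    for n in tree.preorder():
        if n is tree.root or n.is_leaf or n.support is None:
            continue
        side = tree.leaf_set(n)
        if ref in side:
            side = taxa - side
        support_map[side] = n.support
    leaf = tree.find(leaf_label)
    if leaf is None or not leaf.is_leaf:
        raise KeyError(f"leaf {leaf_label!r} not in tree")
    if leaf.parent is tree.root and len(tree.root.children) == 2:
        return tree  # already rooted there
    parent = leaf.parent
    parent.children.remove(leaf)
    leaf.parent = None
    new_root = Node()
    new_root.add(leaf)
    # invert the ancestor path: each former parent becomes a child
    prev = new_root
    cur = parent
    while cur is not None:
        nxt = cur.parent
        if nxt is not None:
            nxt.children.remove(cur)
        cur.parent = None
        prev.add(cur)
        prev = cur
        cur = nxt
    _collapse_unary(new_root)
    rooted = Tree(new_root)
    for n in rooted.preorder():
        if n is rooted.root or n.is_leaf:
            n.support = None
            continue
        side = rooted.leaf_set(n)
        if ref in side:
            side = taxa - side
        n.support = support_map.get(side)
    return rooted.validate()


def midpoint_root(tree: Tree) -> Tree:
    """Root at the leaf most distant (by edge count) from the others'
    centroid — a light stand-in used only when no outgroup exists."""
    # depth-based heuristic: root on the pendant edge of the deepest leaf
    depths = {}
    for leaf in tree.leaves():
        d = 0.0
        n = leaf
        while n.parent is not None:
            d += n.length or 1.0
            n = n.parent
        depths[leaf.label] = d
    deepest = max(sorted(depths), key=lambda k: depths[k])
    return root_at_leaf_edge(tree, deepest)


# ---- orthology ---------------------------------------------------------

@dataclass(frozen=True)
class OrthologyCall:
    candidate_id: str
    verdict: str                   # sall_ortholog | other_salbox | unresolved
    clade: frozenset[str]
    support: Optional[float]


def call_orthology(tree: Tree, candidates: Sequence[str],
                   reference_labels: Mapping[str, str],
                   threshold: float = 0.95) -> list[OrthologyCall]:
    """Classify candidates by the smallest supported clade they share with
    reference sequences.

    Clades are read off the (effectively unrooted) support tree: every edge
    splits the taxa in two, and the candidate's side of a supported edge
    (support > ``threshold``; pendant edges count as fully supported, and
    the whole leaf set acts as the root clade of last resort) is a candidate
    clade.  The smallest such clade containing at least one reference
    decides: all its references Sall → ``sall_ortholog``; none Sall →
    ``other_salbox``; a mixture → ``unresolved``.
    """
    for fam in reference_labels.values():
        if fam not in REFERENCE_FAMILIES:
            raise ValueError(f"unknown reference family {fam!r}")
    leaves = frozenset(tree.leaf_labels())
    missing_refs = set(reference_labels) - leaves
    if missing_refs:
        raise KeyError(f"references absent from tree: {sorted(missing_refs)}")
    # every node below the root stands for one edge of the unrooted tree
    edges: list[tuple[frozenset[str], Optional[float]]] = []
    for node in tree.preorder():
        if node is tree.root:
            continue
        side = tree.leaf_set(node)
        support = 1.0 if node.is_leaf else node.support
        edges.append((side, support))
    calls = []
    for cand in candidates:
        if cand not in leaves:
            raise KeyError(f"candidate {cand!r} absent from tree")
        clades: list[tuple[frozenset[str], Optional[float]]] = []
        for side, support in edges:
            if support is None or support <= threshold:
                continue
            cside = side if cand in side else leaves - side
            clades.append((cside, support))
        clades.append((leaves, None))  # root clade of last resort
        clades.sort(key=lambda cs: (len(cs[0]), tuple(sorted(cs[0]))))
        verdict, clade, sup = "unresolved", frozenset(), None
        for members, support in clades:
            fams = {reference_labels[m] for m in members
                    if m in reference_labels}
            if not fams:
                continue
            clade, sup = members, support
            if fams == {"sall"}:
                verdict = "sall_ortholog"
            elif "sall" not in fams:
                verdict = "other_salbox"
            else:
                verdict = "unresolved"
            break
        calls.append(OrthologyCall(cand, verdict, clade, sup))
    return calls
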