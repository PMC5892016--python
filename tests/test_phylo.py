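"""Domain extraction, NJ trees, bootstrap support, orthology calls."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from spalt import (
    SequenceRecord,
    bootstrap_support,
    call_orthology,
    classify_architecture,
    extract_domains,
    nj_tree,
    write_newick,
)
from spalt.phylo import DomainExtractionError, ExtractionWarning
from spalt.synthetic import make_protein, sem4_like_spec, two_family_dataset
from spalt.trees import Node, Tree, random_binary_tree


# ---------------------------------------------------------------- extraction

def test_extract_planted_zf3_zf4(canonical_protein):
    r = canonical_protein.record
    arch = classify_architecture(r)
    got = extract_domains(r, arch, ["ZF3", "ZF4"])
    s3, s4 = canonical_protein.spans["ZF3"], canonical_protein.spans["ZF4"]
    assert got == r.residues[slice(*s3)] + r.residues[slice(*s4)]


def test_extract_empty_label_set(canonical_protein):
    arch = classify_architecture(canonical_protein.record)
    assert extract_domains(canonical_protein.record, arch, []) == ""


def test_extract_missing_label_nonstrict_warns():
    p = make_protein(sem4_like_spec(seed=4))
    arch = classify_architecture(p.record)
    with pytest.warns(ExtractionWarning, match="ZF2"):
        got = extract_domains(p.record, arch, ["ZF2", "ZF3", "ZF5"],
                              strict=False)
    s3 = arch.get("ZF3").span
    s5 = arch.get("ZF5").span
    assert got == p.record.residues[slice(*s3)] + p.record.residues[slice(*s5)]


def test_extract_missing_label_strict_raises(canonical_protein):
    arch = classify_architecture(canonical_protein.record)
    with pytest.raises(DomainExtractionError):
        extract_domains(canonical_protein.record, arch, ["ZFQ_NOT_A_LABEL"])


# ---------------------------------------------------------------- nj

def _tree_metric(tree: Tree) -> DistanceMatrix:
    labels = tree.leaf_labels()
    n = len(labels)
    # path lengths between leaves
    def path_to_root(leaf):
        path = {}
        node, d = leaf, 0.0
        while node is not None:
            path[id(node)] = d
            d += node.length or 0.0
            node = node.parent
        return path

    paths = {l.label: path_to_root(l) for l in tree.leaves()}
    anc = {l.label: p for l, p in zip(tree.leaves(), paths.values())}
    D = np.zeros((n, n))
    leaves = {l.label: l for l in tree.leaves()}
    for i, j in itertools.combinations(range(n), 2):
        a, b = labels[i], labels[j]
        pa, pb = paths[a], paths[b]
        # find deepest common ancestor on the two root paths
        node = leaves[a]
        da = 0.0
        while id(node) not in pb:
            da += node.length or 0.0
            node = node.parent
        d = da + pb[id(node)]
        D[i, j] = D[j, i] = d
    return DistanceMatrix(D, labels)


def test_nj_recovers_known_quartet_exactly():
    # ((A,B),(C,D)) with pendant lengths 1..4 and internal edge 5
    labels = ["A", "B", "C", "D"]
    lens = dict(zip(labels, [1.0, 2.0, 3.0, 4.0]))
    D = np.zeros((4, 4))
    for i, j in itertools.combinations(range(4), 2):
        a, b = labels[i], labels[j]
        D[i, j] = D[j, i] = lens[a] + lens[b] + \
            (5.0 if (a in "AB") != (b in "AB") else 0.0)
    t = nj_tree(DistanceMatrix(D, labels))
    assert t.bipartitions() == {frozenset({"C", "D"})}
    lengths = {n.label: n.length for n in t.preorder() if n.is_leaf}
    assert lengths == pytest.approx(lens)


def test_nj_three_taxa_closed_form():
    D = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
                       ["A", "B", "C"])
    t = nj_tree(D)
    lengths = {n.label: n.length for n in t.root.children}
    assert lengths["A"] == pytest.approx(1.0)
    assert lengths["B"] == pytest.approx(2.0)
    assert lengths["C"] == pytest.approx(3.0)


def test_nj_rejects_asymmetric_matrix():
    dm = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float),
                        ["A", "B", "C"])
    dm.data[0, 1] = 5.0  # break symmetry behind the container's back
    with pytest.raises(ValueError):
        nj_tree(dm)


def test_nj_exactly_recovers_random_additive_metrics(rng):
    """Topology and additivity: NJ on a tree metric returns that tree."""
    for trial in range(12):
        n = int(rng.integers(4, 9))
        t = random_binary_tree([f"t{i}" for i in range(n)], rng)
        for node in t.preorder():
            if node.parent is not None:
                node.length = float(rng.uniform(0.1, 2.0))
        dm = _tree_metric(t)
        recovered = nj_tree(dm)
        assert recovered.bipartitions() == t.bipartitions()


def test_nj_agrees_with_independent_implementation(rng):
    """Cross-check against scikit-bio's NJ on generic matrices."""
    for trial in range(5):
        n = 7
        labels = [f"L{i}" for i in range(n)]
        M = rng.random((n, n)) * 2 + 0.5
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        dm = DistanceMatrix(M, labels)
        ours = nj_tree(dm).bipartitions()
        sk = skbio_nj(dm)
        taxa, ref = frozenset(labels), min(labels)
        theirs = set()
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = taxa - side
            if 1 < len(side) < len(taxa) - 1:
                theirs.add(side)
        assert ours == theirs


# ---------------------------------------------------------------- bootstrap

def test_clean_two_cluster_signal_gets_full_support():
    recs, refs, cands = two_family_dataset(seed=3, within=0.0)
    tree = bootstrap_support(recs, n_replicates=25, seed=1)
    cluster = frozenset(r for r in refs if refs[r] == "schnurri")
    taxa = frozenset(tree.leaf_labels())
    side = cluster if min(taxa) not in cluster else taxa - cluster
    supports = {n.support for n in tree.preorder()
                if not n.is_leaf and n is not tree.root
                and tree.leaf_set(n) in (cluster, taxa - cluster)}
    assert supports and max(s for s in supports if s is not None) == 1.0


def test_single_replicate_supports_are_zero_or_one():
    recs, _, _ = two_family_dataset(seed=6, n_other=3, n_candidates=1)
    tree = bootstrap_support(recs, n_replicates=1, seed=5)
    sups = [n.support for n in tree.preorder() if n.support is not None]
    assert sups and set(sups) <= {0.0, 1.0}


def test_bootstrap_deterministic_given_seed():
    recs, _, _ = two_family_dataset(seed=8, n_other=3)
    t1 = bootstrap_support(recs, n_replicates=20, seed=11)
    t2 = bootstrap_support(recs, n_replicates=20, seed=11)
    assert write_newick(t1, with_support=True) == \
        write_newick(t2, with_support=True)


def test_supports_bounded(rng):
    recs, _, _ = two_family_dataset(seed=13, within=0.15, between=0.4)
    tree = bootstrap_support(recs, n_replicates=30, seed=2)
    for n in tree.preorder():
        if n.support is not None:
            assert 0.0 <= n.support <= 1.0


# ---------------------------------------------------------------- orthology

def _supported_tree():
    """Hand-built rooted-shape tree: ((cand,sall1,sall2)@1.0,(shn1,shn2)@0.99,out)."""
    root = Node()
    sall = Node(support=1.0)
    for lab in ("cand", "sall1", "sall2"):
        sall.add(Node(label=lab))
    shn = Node(support=0.99)
    for lab in ("shn1", "shn2"):
        shn.add(Node(label=lab))
    root.add(sall)
    root.add(shn)
    root.add(Node(label="out_sall"))
    return Tree(root)


def test_candidate_in_supported_sall_clade():
    tree = _supported_tree()
    refs = {"sall1": "sall", "sall2": "sall", "out_sall": "sall",
            "shn1": "schnurri", "shn2": "schnurri"}
    calls = call_orthology(tree, ["cand"], refs, threshold=0.95)
    assert calls[0].verdict == "sall_ortholog"
    assert calls[0].support == 1.0


def test_candidate_sister_to_schnurri_is_other_salbox():
    root = Node()
    shn = Node(support=0.99)
    shn.add(Node(label="cand"))
    shn.add(Node(label="shn1"))
    shn.add(Node(label="shn2"))
    root.add(shn)
    sall = Node(support=1.0)
    sall.add(Node(label="sall1"))
    sall.add(Node(label="sall2"))
    root.add(sall)
    refs = {"sall1": "sall", "sall2": "sall",
            "shn1": "schnurri", "shn2": "schnurri"}
    calls = call_orthology(Tree(root), ["cand"], refs, threshold=0.95)
    assert calls[0].verdict == "other_salbox"


def test_unsupported_placement_is_unresolved():
    root = Node()
    sall = Node(support=0.60)  # below threshold
    sall.add(Node(label="cand"))
    sall.add(Node(label="sall1"))
    root.add(sall)
    shn = Node(support=0.55)   # also below threshold
    shn.add(Node(label="shn1"))
    shn.add(Node(label="shn2"))
    root.add(shn)
    root.add(Node(label="sall2"))
    refs = {"sall1": "sall", "sall2": "sall",
            "shn1": "schnurri", "shn2": "schnurri"}
    calls = call_orthology(Tree(root), ["cand"], refs, threshold=0.95)
    # every supported clade containing the candidate holds both reference
    # classes, so the call falls through to unresolved
    assert calls[0].verdict == "unresolved"


def test_complement_of_supported_outgroup_edge_counts_as_clade():
    """An edge separating the non-Sall cluster also delimits, on its other
    side, the Sall clade (outgroup rooting read off the unrooted tree)."""
    root = Node()
    sall = Node(support=0.60)
    sall.add(Node(label="cand"))
    sall.add(Node(label="sall1"))
    root.add(sall)
    shn = Node(support=0.99)
    shn.add(Node(label="shn1"))
    shn.add(Node(label="shn2"))
    root.add(shn)
    root.add(Node(label="sall2"))
    refs = {"sall1": "sall", "sall2": "sall",
            "shn1": "schnurri", "shn2": "schnurri"}
    calls = call_orthology(Tree(root), ["cand"], refs, threshold=0.95)
    assert calls[0].verdict == "sall_ortholog"
    assert calls[0].clade == frozenset({"cand", "sall1", "sall2"})


def test_missing_candidate_raises():
    tree = _supported_tree()
    refs = {"sall1": "sall", "shn1": "schnurri", "shn2": "schnurri",
            "sall2": "sall", "out_sall": "sall"}
    with pytest.raises(KeyError):
        call_orthology(tree, ["ghost"], refs)


def test_planted_sall_candidates_all_recovered():
    """Synthetic two-family dataset: every planted Sall candidate is called
    sall_ortholog at threshold 0.95 with 200 replicates."""
    recs, refs, cands = two_family_dataset(seed=17)
    tree = bootstrap_support(recs, n_replicates=200, seed=23)
    calls = call_orthology(tree, cands, refs, threshold=0.95)
    assert all(c.verdict == "sall_ortholog" for c in calls)


# ---------------------------------------------------------------- rooting

def test_outgroup_rooting_preserves_leaves_and_supports():
    from spalt.phylo import root_at_leaf_edge

    recs, refs, cands = two_family_dataset(seed=41, n_other=3)
    tree = bootstrap_support(recs, n_replicates=20, seed=3)
    rooted = root_at_leaf_edge(tree, "Schnurri_ref0")
    assert sorted(rooted.leaf_labels()) == sorted(tree.leaf_labels())
    assert {c.label for c in rooted.root.children if c.is_leaf} == \
        {"Schnurri_ref0"}
    # bipartition supports survive the rerooting
    before = {}
    taxa = frozenset(tree.leaf_labels())
    ref = min(taxa)
    for n in tree.preorder():
        if n is tree.root or n.is_leaf or n.support is None:
            continue
        side = tree.leaf_set(n)
        before[side if ref not in side else taxa - side] = n.support
    for n in rooted.preorder():
        if n is rooted.root or n.is_leaf or n.support is None:
            continue
        side = rooted.leaf_set(n)
        key = side if ref not in side else taxa - side
        if key in before:
            assert n.support == before[key]
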