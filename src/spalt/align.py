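"""Global protein alignment: affine-gap pairwise and progressive multiple.

A desk-scale replacement for interactive alignment tooling: Needleman–
Wunsch/Gotoh pairwise alignment under a standard substitution table
(BLOSUM62 by default), and a progressive aligner whose guide order comes
from single-linkage clustering of pairwise distances, merging profiles
with the same affine scoring.  Tie-breaking is deterministic everywhere:
the traceback prefers a substitution over a gap, then a gap in the first
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .records import SequenceRecord

GAP = "-"
NEG_INF = float("-inf")


def load_score_table(name: str = "BLOSUM62") -> dict[tuple[str, str], float]:
    """A substitution score table as a plain dict, symmetric, X included."""
    mat = substitution_matrices.load(name)
    table: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = float(mat[a, b])
    return table


@dataclass
class Alignment:
    """Rows of equal length mapping record id -> gapped residue string."""

    rows: dict[str, str]

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def _check(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        assert len(lengths) <= 1, "ragged alignment"

    def degapped(self, rid: str) -> str:
        return self.rows[rid].replace(GAP, "")

    def column(self, j: int) -> list[str]:
        return [r[j] for r in self.rows.values()]


def pairwise_align(a: str, b: str,
                   table: dict[tuple[str, str], float] | None = None,
                   gap_open: float = -10.0, gap_extend: float = -1.0,
                   ids: tuple[str, str] = ("a", "b")) -> tuple[Alignment, float]:
    """Optimal global alignment with affine gaps (Gotoh algorithm).

    A gap of length L costs ``gap_open + (L-1)*gap_extend`` (both
    parameters negative).  Returns the alignment and its score; on score
    ties the traceback prefers match/mismatch, then a gap in ``a``.
    """
    if not a or not b:
        raise ValueError("pairwise_align requires non-empty sequences")
    if table is None:
        table = load_score_table()
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG_INF)   # a[i-1] ~ b[j-1]
    Ga = np.full((n + 1, m + 1), NEG_INF)  # gap in a (consumes b)
    Gb = np.full((n + 1, m + 1), NEG_INF)  # gap in b (consumes a)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        Ga[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        Gb[i, 0] = gap_open + (i - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = table[(a[i - 1], b[j - 1])]
            M[i, j] = max(M[i - 1, j - 1], Ga[i - 1, j - 1], Gb[i - 1, j - 1]) + s
            Ga[i, j] = max(M[i, j - 1] + gap_open, Ga[i, j - 1] + gap_extend,
                           Gb[i, j - 1] + gap_open)
            Gb[i, j] = max(M[i - 1, j] + gap_open, Gb[i - 1, j] + gap_extend,
                           Ga[i - 1, j] + gap_open)
    score = max(M[n, m], Ga[n, m], Gb[n, m])
    # traceback; preference order M (substitution) > Ga (gap in a) > Gb
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    state = max((("M", M[n, m]), ("Ga", Ga[n, m]), ("Gb", Gb[n, m])),
                key=lambda kv: (kv[1], kv[0] == "M", kv[0] == "Ga"))[0]
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = table[(a[i - 1], b[j - 1])]
            target = M[i, j] - s
            i, j = i - 1, j - 1
            if M[i, j] == target:
                state = "M"
            elif Ga[i, j] == target:
                state = "Ga"
            else:
                state = "Gb"
        elif state == "Ga":
            out_a.append(GAP)
            out_b.append(b[j - 1])
            here = Ga[i, j]
            j -= 1
            if M[i, j] + gap_open == here:
                state = "M"
            elif Ga[i, j] + gap_extend == here:
                state = "Ga"
            else:
                state = "Gb"
        else:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            here = Gb[i, j]
            i -= 1
            if M[i, j] + gap_open == here:
                state = "M"
            elif Gb[i, j] + gap_extend == here:
                state = "Gb"
            else:
                state = "Ga"
        if i == 0 and j > 0:
            state = "Ga"
        elif j == 0 and i > 0:
            state = "Gb"
    aln = Alignment({ids[0]: "".join(reversed(out_a)),
                     ids[1]: "".join(reversed(out_b))})
    aln._check()
    return aln, float(score)


def _aligned_distance(aln: Alignment) -> float:
    """Fraction of alignment columns that are not identical matches."""
    r1, r2 = (aln.rows[k] for k in aln.ids)
    diff = sum(1 for x, y in zip(r1, r2) if x != y or x == GAP)
    return diff / len(r1)


def _profile_align(p: Alignment, q: Alignment,
                   table: dict[tuple[str, str], float],
                   gap_open: float, gap_extend: float) -> Alignment:
    """Gotoh on two profiles; column score = mean pairwise substitution
    score, a residue against a gap scoring ``gap_extend``, gap-gap zero."""
    pc = [p.column(j) for j in range(p.length)]
    qc = [q.column(j) for j in range(q.length)]

    def colscore(ci: list[str], cj: list[str]) -> float:
        tot = 0.0
        cnt = 0
        for x in ci:
            for y in cj:
                if x == GAP and y == GAP:
                    s = 0.0
                elif x == GAP or y == GAP:
                    s = gap_extend
                else:
                    s = table[(x, y)]
                tot += s
                cnt += 1
        return tot / cnt

    n, m = len(pc), len(qc)
    M = np.full((n + 1, m + 1), NEG_INF)
    Ga = np.full((n + 1, m + 1), NEG_INF)
    Gb = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        Ga[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        Gb[i, 0] = gap_open + (i - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = colscore(pc[i - 1], qc[j - 1])
            M[i, j] = max(M[i - 1, j - 1], Ga[i - 1, j - 1], Gb[i - 1, j - 1]) + s
            Ga[i, j] = max(M[i, j - 1] + gap_open, Ga[i, j - 1] + gap_extend,
                           Gb[i, j - 1] + gap_open)
            Gb[i, j] = max(M[i - 1, j] + gap_open, Gb[i - 1, j] + gap_extend,
                           Ga[i - 1, j] + gap_open)
    # traceback into a merged column path
    i, j = n, m
    state = max((("M", M[n, m]), ("Ga", Ga[n, m]), ("Gb", Gb[n, m])),
                key=lambda kv: (kv[1], kv[0] == "M", kv[0] == "Ga"))[0]
    path: list[str] = []
    while i > 0 or j > 0:
        path.append(state)
        if state == "M":
            s = colscore(pc[i - 1], qc[j - 1])
            target = M[i, j] - s
            i, j = i - 1, j - 1
            state = ("M" if M[i, j] == target
                     else "Ga" if Ga[i, j] == target else "Gb")
        elif state == "Ga":
            here = Ga[i, j]
            j -= 1
            state = ("M" if M[i, j] + gap_open == here
                     else "Ga" if Ga[i, j] + gap_extend == here else "Gb")
        else:
            here = Gb[i, j]
            i -= 1
            state = ("M" if M[i, j] + gap_open == here
                     else "Gb" if Gb[i, j] + gap_extend == here else "Ga")
        if i == 0 and j > 0:
            state = "Ga"
        elif j == 0 and i > 0:
            state = "Gb"
    path.reverse()
    rows = {rid: [] for rid in list(p.ids) + list(q.ids)}
    pi = qi = 0
    for st in path:
        use_p = st in ("M", "Gb")
        use_q = st in ("M", "Ga")
        for rid in p.ids:
            rows[rid].append(p.rows[rid][pi] if use_p else GAP)
        for rid in q.ids:
            rows[rid].append(q.rows[rid][qi] if use_q else GAP)
        pi += use_p
        qi += use_q
    merged = Alignment({k: "".join(v) for k, v in rows.items()})
    merged._check()
    return merged


def progressive_align(seqs: Sequence[SequenceRecord],
                      table: dict[tuple[str, str], float] | None = None,
                      gap_open: float = -10.0,
                      gap_extend: float = -1.0) -> Alignment:
    """Progressive multiple alignment.

    Pairwise distances (fraction of non-identical columns in the optimal
    pairwise alignments) feed single-linkage clustering; profiles are merged
    in that order with the same affine scoring.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_align requires at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if table is None:
        table = load_score_table()
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln, _ = pairwise_align(seqs[i].residues, seqs[j].residues,
                                    table, gap_open, gap_extend)
            d = _aligned_distance(Alignment({"a": aln.rows["a"], "b": aln.rows["b"]}))
            dist[i, j] = dist[j, i] = d
    if n == 2:
        aln, _ = pairwise_align(seqs[0].residues, seqs[1].residues,
                                table, gap_open, gap_extend,
                                ids=(ids[0], ids[1]))
        return aln
    Z = linkage(squareform(dist, checks=False), method="single")
    profiles: dict[int, Alignment] = {
        i: Alignment({ids[i]: seqs[i].residues}) for i in range(n)
    }
    for k, (left, right, _, _) in enumerate(Z):
        a = profiles.pop(int(left))
        b = profiles.pop(int(right))
        profiles[n + k] = _profile_align(a, b, table, gap_open, gap_extend)
    (msa,) = profiles.values()
    # restore input row order
    msa = Alignment({rid: msa.rows[rid] for rid in ids})
    msa._check()
    assert msa.length >= max(len(s.residues) for s in seqs)
    return msa


def trim_alignment(msa: Alignment, max_gap_fraction: float = 0.5) -> Alignment:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction`` — the
    automated stand-in for by-eye removal of ambiguously aligned regions."""
    keep = []
    nrow = len(msa.rows)
    for j in range(msa.length):
        gaps = sum(1 for x in msa.column(j) if x == GAP)
        if gaps / nrow <= max_gap_fraction:
            keep.append(j)
    return Alignment({rid: "".join(row[j] for j in keep)
                      for rid, row in msa.rows.items()})
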