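# Methods

## The Sall domain grammar

Sall (Spalt-like) proteins are multi-zinc-finger transcription factors
found across Bilateria. The package models them as a linear grammar of
sequence features, N→C:

    NURD – ZF1 – POLYQ – ZF2 – [pre-ZF3 consensus] – ZF3 – ZF3A – ZF4 – ZF5 – ZF6

* **NURD** — a 12-residue N-terminal segment that recruits the NuRD
  histone-deacetylase complex.
* **ZF1** — a single zinc finger of the C2HC class.
* **POLYQ** — a glutamine-rich tract between ZF1 and ZF2.
* **ZF2–ZF5** — C2H2 zinc-finger *pairs* joined by a short "H/C link"
  spacer; the C-terminal finger of each pair carries the 8-residue
  Sal-box `FTTKGNLK` (shared with Schnurri, PRDII-BF1 and HIVEP1).
* **ZF3A** — the single extra finger associated with the ZF3 pair.
* **ZF6** — a single Sal-box-free C2H2 finger at the C terminus.
* The 14-residue consensus `SETSKLQQLVENID` sits just N-terminal of the
  ZF3 pair and serves as the ZF3 anchor during classification.

### Scanning

Zinc fingers are matched against the spacing patterns
`C-x(1,5)-C-x(10,14)-H-x(3,6)-H` (C2H2) and `…-C` (C2HC). These are
standard C2H2-family spacing windows, wide enough to admit the
Sal-box-bearing fingers; all four bounds are `ScanParams` fields. The
domains in the source comparative work were delimited by alignment and
eye, so the pattern itself is a design choice of this package. Overlapping
candidate spans are resolved deterministically: leftmost first, longest on
equal starts, C2H2 over C2HC on identical spans. Fuzzy motifs (Sal-box,
pre-ZF3 consensus, NuRD motif) are fixed-length Hamming-distance scans;
overlaps keep the fewest-mismatch window, leftmost on ties. Poly-Q tracts
are maximal intervals of length ≥ 6 with Q fraction ≥ 0.8 and Q at both
ends — thresholds chosen so incidental `QQ` runs do not fire.

Key defaults (all in `ScanParams`):

| parameter | default | why |
|---|---|---|
| `salbox_max_mismatch` | 1 | the box is well conserved but exactness is not guaranteed; reporting tolerance |
| `salbox_member_mismatch` | 0 | pairing and `contains_salbox` demand an exact box |
| `polyq_min_length`, `polyq_min_fraction` | 6, 0.8 | suppress incidental short Q runs |
| `max_link` | 12 residues | the H/C link is short; modelled as a maximum spacer because no published link consensus is available here |
| `nurd_window` | 30 residues | the NuRD motif is N-terminal by definition |
| `nurd_consensus` | `MSRKTAKPVDLG` | **an implementation placeholder**: only the motif's length (12) is a modelled fact; the consensus string is config-supplied |
| `pre_zf3_window`, `zf3a_window` | 40, 40 | generous neighbourhoods tying the consensus / associated finger to the ZF3 pair |

Finger pairing is greedy left-to-right: each exact-Sal-box C2H2 finger
becomes a C-finger; the nearest preceding unpaired Sal-box-free C2H2
finger within `max_link` becomes its N-finger, otherwise the pair is
degenerate (`lost_N`). A `lost_C` degenerate pair is representable but is
never produced by the pairing step alone — it requires architecture-level
context.

### Classification

Labels are assigned by an anchored cascade (NURD → ZF1 → POLYQ → ZF3
anchor → remaining pairs → ZF6 → ZFX). The ZF3 anchor is found by the
pre-ZF3 consensus first, by the associated finger (then labelled ZF3A)
second, and positionally (with an `ambiguous_no_zf3_anchor` flag) last.
Pairs before the anchor are ZF2; two pairs after it are ZF4 and ZF5. A
*single* trailing pair is genuinely ambiguous without sequence homology;
it is labelled ZF5 — ZF4 is the more commonly lost of the two across the
surveyed taxa — and flagged `ambiguous_zf4_zf5`. ZF6 is the last single
Sal-box-free C2H2 finger C-terminal to all pairs; anything unaccounted for
is ZFX. Conflicting (overlapping) assignments are dropped in favour of the
earlier rule and recorded as flags, never silently.

Presence/absence matrices count degenerate pairs as present (a modified
domain is still the domain). Every matrix entry carries a provenance tag:
`scanned` (from sequence), `text_stated` (encoded survey fact) or
`default_present` (unstated, defaulted under the observation that the
Sall domain arrangement is highly consistent across bilaterians).

## Phylogenetics

The original orthology analysis used Bayesian inference (BEAST, JTT+G,
strict clock) on domain-restricted alignments and accepted a candidate as
an ortholog when it grouped with references of known identity at posterior
probability > 0.95. At desk scale this package substitutes a deterministic
pipeline while keeping the decision rule:

1. **Domain restriction** — `extract_domains` concatenates ZF3+ZF4 (the
   only domains shared by all Sal-box proteins) for family sorting, or
   ZF2+ZF3+ZF5 for Sall-only analyses.
2. **Alignment** — Needleman–Wunsch/Gotoh affine-gap global alignment
   (BLOSUM62, gap open −10, extend −1). The traceback prefers a
   substitution over a gap, then a gap in the first sequence, so results
   are deterministic. Progressive multiple alignment merges profiles in
   single-linkage order of pairwise distances with the same scoring;
   profile column scores are mean pairwise substitution scores with
   residue-vs-gap scored at the gap-extension penalty.
3. **Trimming** — columns with gap fraction > 0.5 are dropped: an
   automated stand-in for the original by-eye removal of ambiguous
   regions.
4. **Distances** — p-distance, Poisson correction `d = −ln(1−p)`, or the
   gamma-corrected `d = α((1−p)^(−1/α) − 1)` standing in for a full
   rate-heterogeneity model. Saturated pairs (p = 1) are capped at a
   configurable maximum (default 10) with a warning.
5. **Tree** — neighbor joining with the Studier–Keppler Q criterion;
   negative branch-length estimates are clamped to zero; Q ties resolve to
   the lowest-index pair, so output is deterministic for a given label
   order.
6. **Support** — nonparametric bootstrap: alignment columns resampled with
   replacement per replicate (200 by default), support = fraction of
   replicate trees containing each internal bipartition of the full-data
   tree. Seed-deterministic.
7. **Orthology** — clades are read off the unrooted support tree: each
   supported edge (support > 0.95; pendant edges are trivially supported)
   splits the taxa, and the candidate's side is a candidate clade. The
   smallest such clade containing a reference decides: all-Sall →
   `sall_ortholog`, none-Sall → `other_salbox`, mixed (or only the
   root clade) → `unresolved`. Reading both sides of each edge makes the
   call independent of root placement; outgroup/deepest-leaf rooting
   helpers exist for display.

Bootstrap proportions are not posterior probabilities; the 0.95 threshold
is retained as a decision rule, not as a claim of equivalence. Published
clade supports from the original 40+-taxon Bayesian analysis are
explicitly not reproduced here (that would require the original sequence
set and an MCMC run); the package's tests instead verify the machinery
against exact oracles (exhaustive alignment enumeration for short
sequences, exact recovery of additive metrics, an independent NJ
implementation) and full candidate recovery on synthetic two-family data.

## Ancestral reconstruction

Characters are binary domain presences on a rooted species tree.

* **Fitch parsimony** uses Hartigan's generalisation, so multifurcating
  nodes are scored exactly; the change count is property-tested against
  brute-force enumeration on all trees up to 8 leaves. Ambiguous internal
  states are kept as sets; for event mapping a single most-parsimonious
  resolution is chosen by a documented rule — prefer presence at the root,
  then inherit the parent's state wherever co-optimal — mirroring the
  plesiomorphy-then-loss reading of Sall domain evolution.
* **Dollo parsimony** places each character's single gain at the last
  common ancestor of the carrier taxa and the losses on the highest
  branches consistent with tip states, minimising losses subject to the
  single-gain constraint. A character absent from every leaf yields an
  all-zero reconstruction with a warning. One consequence worth knowing:
  a loss on a branch directly below the root is parsimony-equivalent to a
  later gain and is reconstructed as the latter (the gain node simply
  drops below the root).

Events are reported per branch (named by the child node; the root branch
carries root-state gains), sorted by preorder branch index then character.
`count_node_domains` counts ZF1–ZF6 only: ZF3A is an associated finger,
and NURD/POLYQ are not zinc fingers.

## The bilaterian fixture

`fixtures.fixture_matrix()` encodes the cross-taxon survey of Sall domains
over 25 taxa (including the Drosophila Salm/Salr and vertebrate Sall1–4
paralogs as terminal sister leaves) and 9 domain classes. Only facts the
survey states in prose are encoded (`text_stated`); everything else is
`default_present`. Partially conserved poly-Q tracts (bryozoan, tunicate)
and one-finger-modified pairs count as present. `fixtures.fixture_tree()`
hard-codes the accepted bilaterian backbone — Xenacoelomorpha sister to
Nephrozoa, then Protostomia (Spiralia + Ecdysozoa) and Deuterostomia —
with within-clade arrangements chosen as a plausible fixture, not
inferred. Dollo parsimony on this fixture reconstructs all six ZF classes
at the bilaterian root (the package's headline reconstruction) and places
ZF6 losses on the deuterostome, nematode, priapulid and insect branches
(plus the platyhelminth, which retains only ZF3 and ZF4).

## Synthetic data

`synthetic` plants the full grammar into generated sequences: literal
finger/motif building blocks (the Sal-box and pre-ZF3 consensus are the
published strings; fingers are fixed 21-mers obeying the spacing
patterns), linkers drawn uniformly from the 20 amino acids minus C, H and
Q (so the background can neither spell a finger nor extend a poly-Q), and
point substitutions at a configurable per-residue rate. Zinc-coordinating
positions, the Sal-box, and planted consensus motifs are protected from
noise by default (`protect_anchors=False` disables this), and replacement
letters are drawn from the same C/H/Q-free background, so noise can only
destroy planted features, never create new ones; with a fixed seed the
mutated position set grows monotonically with the rate, which is what
makes the recovery-vs-noise property test meaningful.

`evolve_family` realises one root protein and evolves it down a tree:
per-branch feature excision according to a loss plan (a feature cannot be
lost twice on one path) and per-branch substitutions scaled by branch
length, so divergence accumulates with path depth. The generator does not
emulate indels, substitution-matrix-biased exchange, rate variation among
sites, or domain gain — passing tests therefore demonstrate correctness of
the machinery on grammar-faithful sequences, not robustness to the full
messiness of real proteins (partial sequences, divergent spacing outside
the configured windows, compositional bias).

`two_family_dataset` builds the orthology test case: a Sall cluster
(references + candidates, 4% within-cluster divergence) and a distant
Sal-box cluster (60% divergence from the Sall base), 70 residues long —
separations in line with the deep divergence between Sall and the other
Sal-box families.

## Problem sizes and runtime

All shipped analyses are desk-scale by design: the fixture reconstruction
(25 taxa × 9 characters) and the grammar constants run in well under a
second; property tests use trees of ≤ 8–12 leaves, sequences of ≤ 200
residues, exhaustive oracles on sequences of ≤ 8 residues, and bootstrap
runs of 10 sequences × 200 replicates (a few seconds). The full test
suite completes in a few seconds on one CPU.

## Known limitations

* ZF4 vs ZF5 cannot be told apart positionally when only one survives;
  such architectures are labelled ZF5 and flagged (see classification).
* The NuRD-motif consensus string is a configurable placeholder; only its
  length and N-terminal location are modelled facts.
* Bootstrap-on-NJ support is a proxy, not a reimplementation, of the
  original Bayesian posterior supports.
* Gene-tree/species-tree reconciliation is out of scope: paralogs sit in
  the fixture tree as terminal sister leaves at their species' positions.
* The Newick writer emits internal-node supports as labels; trees with
  both internal names and supports keep only the support when asked to
  write supports.
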