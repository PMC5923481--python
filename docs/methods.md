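# Methods

This note documents the models, statistics, defaults and design choices
behind `repchimera`, and what the simulation-based tests do and do not
demonstrate about real data.

## Domain splitting

The pipeline assumes a two-domain architecture with the helicase domain
C-terminal and opening at the Walker A (P-loop) motif.  The split anchor
is found on the column-wise majority consensus of the full-length
alignment (most frequent non-gap residue per column, ties alphabetical —
a deterministic anchor), matched against the residue-class pattern
`[GA]-x(4)-G-K-[ST]`.  The search is restricted to the C-terminal half of
the ungapped consensus to avoid spurious P-loop-like matches in the
nuclease domain; the first match wins and additional matches only warn.
The match position is mapped through all-gap columns back to an alignment
column; that column begins the helicase block, so the blocks partition the
alignment exactly.

Trimming (drop columns whose non-gap fraction is below
`gap_keep_fraction`, default 0.2, the TrimAl gap-threshold semantics with
the boundary kept) is applied *after* splitting, and the split is located
on the untrimmed alignment: trimming first could delete motif columns and
shift the anchor.  Both orders are reachable through the library API if a
user prefers the other convention.  Connectedness scoring uses the
untrimmed, degapped domain sequences — similarity ranking needs whole
domains, not trimmed columns; trimming only precedes distance/tree
estimation, where noisy sparse columns hurt.

## Connectedness

For each protein and each domain, every other protein is scored by
Smith–Waterman local alignment (BLOSUM62, gap open −11, extend −1) and
ranked score-descending with id-ascending tie-breaks, so the ranking is
bit-reproducible.  The statistic depends only on hit order, not on the
scoring engine, so a profile search (phmmer via pyhmmer) can be swapped in
behind the same contract; the default backend is chosen for determinism
and zero external state.

The top set is the first `k = max(1, floor(top_fraction · H))` hits
(`top_fraction` default 0.2; `H` = number of non-self hits; the clamp
keeps tiny databases defined).  The score is `|N ∩ H| / k` over the two
domains' top sets — the probability that a top hit of one domain is also a
top hit of the other.  When the two sets differ in size (possible with the
pluggable backend) the larger size is the denominator; a Jaccard variant
(`|∩| / |∪|`) is available behind a flag.  Scores below `score_threshold`
(default 0.2) flag likely recombination.  "Self" means the identical
record id only; no same-genome grouping is attempted.

## Distances, trees, supports

Per-domain trees are built by neighbor joining on saturation-corrected
p-distances: `d = −ln(1 − min(p, 0.95))` with `p` the mismatch fraction
over columns where both sequences hold a residue.  The 0.95 cap keeps
near-saturated pairs finite (d ≤ ~3.0).  Pairs sharing fewer than 20
columns are set to the matrix maximum with a warning; zero shared columns
is an error.  NJ uses the standard Q criterion with deterministic
lowest-index tie-breaking and clamps negative branch-length estimates to
zero; on additive matrices it provably recovers the generating topology,
which the tests exercise.

Branch support is a column-resampling bootstrap: each replicate resamples
alignment columns with replacement, rebuilds the NJ tree, and the support
of an internal edge is the percentage of replicates containing its
bipartition (default 100 replicates).  Maximum-likelihood trees with
aBayes posteriors can be imported instead — Newick internal labels are
read as supports, and labels that are all ≤ 1 are rescaled ×100 to the
percentage convention.  Edges below `support_collapse` (default 70%) are
contracted into polytomies before any incongruence measurement; unknown
supports are retained with a warning rather than guessed.

## Incongruence

Two complementary detectors mirror two observable consequences of a
domain swap.

**Tanglegram crossings** summarize global disagreement.  Leaf orders are
chosen to minimize inter-tree line crossings.  Fixing one tree's order,
the optimal rotation of the other decomposes into independent per-node
choices (crossings between two child blocks depend only on their relative
order), so each node's children are reordered exactly (exhaustively up to
6 children, barycenter beyond).  Small instances — one tree with ≤ 4096
rotation states — are solved to the global optimum by enumerating that
tree's rotations against exact reordering of the other; larger instances
alternate exact one-side reordering until no improvement.  Tests verify
global optimality against exhaustive rotation enumeration for trees up to
8 leaves.

**Leaf displacement** makes the visual "this leaf sits somewhere else"
judgement reproducible.  For each leaf, in each collapsed domain tree, the
tree is rooted at the leaf's farthest point (branch-length distance, ties
by label) and the leaf's neighborhood is the smallest clade containing it
plus at least `neighborhood_min` (default 5) other leaves.  Displacement
is one minus the Jaccard overlap of the two neighborhoods; values above
`displacement_threshold` (default 0.8) flag the leaf.  The statistic is
symmetric in the trees and insensitive to leaf order.  The 0.8 default was
calibrated on simulations: planted swaps across divergent clades score
near 1.0, resident leaves stay below ~0.3 unless collapse reshapes their
whole neighborhood.

## Calling, purging, grouping

A protein flagged by both detectors is a `chimera`; by exactly one,
`review`; by neither, `clean`.  Conflicting evidence is never
auto-resolved — the review tier exists precisely because the two
detectors see different timescales (hit overlap resolves recent swaps
among close relatives; tree displacement catches older events).  A
`--strict` mode folds review into chimera for conservative purging.  The
default purge removes only the chimera tier.

Supported groups are read from the purged, rebuilt full-length tree.  The
collapsed tree is treated as unrooted; its *center* — the internal node
minimizing the maximum path length to any leaf — is the natural origin
because divergent clades radiate from near that point and unresolved deep
edges have already collapsed into it.  A group is a maximal subtree off
the center with at least `min_group_size` (default 5) leaves whose stem
and every internal edge carry support at or above the collapse threshold;
maximality makes groups disjoint.  This formulation deliberately avoids
rooting heuristics that can promote "everything except one clade" into a
spurious supersized group, and avoids re-rooting operations that detach
supports from their edges.

## The simulator

The generator produces what the detector assumes and nothing more:

- **Guide tree**: `n_clades` (default 4) clades of `taxa_per_clade`
  (default 12) taxa radiate from a single root on stems of
  `inter_clade_divergence / 2` (default 1.5/2 substitutions/site), so the
  deep backbone is a hard polytomy — deliberately, since the real
  motivating datasets have essentially unresolvable deep structure.
  Within-clade topologies are random ultrametric trees with leaves
  `intra_clade_divergence / 2` (default 0.4/2) below the clade root.
- **Sequences**: nuclease 160 aa, helicase 120 aa.  Per branch of length
  `t`, each site is replaced with probability `1 − exp(−t)` by a draw from
  the Robinson–Robinson background frequencies; motif sites never mutate.
  The helicase opens with Walker A `GPPGTGKT` at offset 0 (so the planted
  split column equals the nuclease length), plus Walker B, motif C and an
  arginine-finger motif; the nuclease carries motifs I–III stand-ins.
  Root sequences are background draws, redrawn if the Walker A pattern
  occurs anywhere outside its planted position, keeping the anchor unique.
- **Chimeras**: exactly `floor(fraction · n)` taxa, chosen uniformly, have
  the helicase replaced by the pre-swap helicase of a donor drawn
  uniformly from a uniformly chosen *other* clade; the truth table records
  each taxon's domain clades.

What the simulator does **not** emulate: indels and alignment error (the
output is gap-free; the aligner is external in real use), among-site rate
variation, amino-acid exchangeability structure (replacements ignore the
current residue), compositional drift between clades, partial-domain
breakpoints, and same-clade (short-range) swaps.  Passing the
simulation-based tests therefore shows the detectors recover *divergent*
domain swaps under clean alignments; it does not certify performance on
recent intra-clade recombination (which both detectors are in principle
blind to, as the neighborhoods and hit sets coincide) or on badly aligned
real data.

## Numerical and reproducibility choices

- All randomness flows from a single seed: the simulator spawns
  independent child seeds per domain and for chimera placement; the
  pipeline spawns per-tree bootstrap seeds.  Equal input, config and seed
  give byte-identical report bundles (floats are written with fixed
  6-decimal formatting; no timestamps).
- Ties everywhere break deterministically (alphabetical ids, lowest index
  pairs, first pattern match).
- Logo matrices use frequencies over non-gap, non-X residues; information
  is `log2 20 − H` bits with no small-sample correction (exposed as the
  natural place for one, but the default is the simplest defensible
  choice); all-gap columns report zero information and a flag.
- Simulation sizes in tests and in the acceptance script (48 taxa, 280
  columns, 100 bootstrap replicates, 10 replicate runs) are chosen so the
  whole suite completes on a laptop-class single core in about a minute
  while keeping every clade large enough (12 taxa) for the default
  neighborhood size of 5.

## Known limitations

- NJ + bootstrap is a deliberate substitute for maximum-likelihood
  inference; imported ML trees are first-class inputs, but the built-in
  trees will under-resolve short deep branches.
- The connectedness denominator reads "total number of hits" as the
  top-list size `k`, which matches the probability interpretation of the
  score; a Jaccard option covers the alternative reading.
- The displacement statistic is a surrogate for expert tanglegram
  inspection; its threshold is simulation-calibrated, not validated
  against curated expert calls.
- Group labels (`group1`, `group2`, …) are positional, not taxonomic;
  naming recovered groups is interpretation and out of scope.
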