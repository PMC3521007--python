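# Methods

This note records the models, algorithmic choices and defaults behind
`hgtscan`, and what the synthetic benchmarks do and do not demonstrate.

## Kingdom assignment

Sequences are classified by containment of diagnostic clade names in
their ordered lineage (root-first), case-insensitively and at any
position: `Bacteria` → Bacteria, `Archaea` → Archaea, `Viridiplantae` →
Plantae, `Eukaryota` without `Viridiplantae` → OtherEukaryote, anything
else → Unknown. The rule table is configurable; when several names match,
the most specific wins (a plant lineage contains both `Eukaryota` and
`Viridiplantae`). No live taxonomy service is consulted: lineages come
from the input TSV, which keeps every run reproducible offline.

## The screen: when is a leaf "wrapped" in a foreign kingdom?

The screen operates on a rooted tree (configured outgroup first, midpoint
rooting as fallback) and on *maximal uniform groups* — maximal clades
whose known-kingdom leaves all share one kingdom; a candidate group is
typically a single leaf or a small clade. Unknown-kingdom leaves never
become candidates and never count toward composition.

A group G with kingdom k is called for host kingdom K ≠ k when two
independent conditions hold:

1. **Wrap test (local).** Walking away from G — first its sibling
   subtrees, then each successive ancestor's siblings — the *two nearest
   informative directions* must both have K as the strict majority of
   their known leaves. Leaves of G's same-kingdom peer groups are
   excluded from these majorities, so two transfers landing side by side
   cannot hide each other. The test is provably exact on
   kingdom-monophyletic trees: all leaves of a monophyletic kingdom lie
   in a single direction from any vantage point outside it, so no group
   can see K-majorities on two sides. This is the formal reading of
   "nested inside another kingdom's branches": host-kingdom evidence on
   at least two sides of the attachment point, rather than mere
   sisterhood.

2. **Host region (global).** G must lie strictly inside a *K host
   region*: in an exclusive top-down partition starting from the root's
   children, a clade is claimed by the strict-majority kingdom of its
   known leaves when that kingdom has ≥ `min_native` members (default 3)
   and the clade's purity — computed after setting aside the leaves of
   non-K groups that pass the wrap test for K — reaches the threshold
   (default 1.0). Descent stops at a claimed clade, so a region can
   never sit inside another kingdom's region. This mirrors cutting
   "kingdom-specific subtrees" before reading off the intruders, and it
   is what keeps native groups sandwiched between two transfers from
   being miscalled: they sit inside their own kingdom's region.

Each candidate leaf is reported once with its smallest qualifying host
clade (the nearest ancestor whose non-candidate known leaves meet the
purity and `min_native` thresholds; the root, where direction is
ambiguous, never qualifies). Candidates whose aligned fragment is shorter
than `min_fragment_length` (default 300 aa, the usual cutoff for
fragmentary Pfam entries) are dropped; candidates with no recorded length
are kept but flagged.

Both detection parameters are monotone: raising the purity threshold or
`min_native` can only shrink the candidate set.

## Alignment ensemble scoring

An ensemble is a set of alternative alignments of identical sequences.
The unit of comparison is the aligned residue pair
((sequence A, position i), (sequence B, position j)); an alignment with L
columns asserts Σ k(k−1)/2 pairs, k being the non-gap count per column.

- `overlap_score(a, b) = 2|a∩b| / (|a|+|b|)` (1 for two empty sets).
- `MOS(A)` = mean over A's pairs of the fraction of the *other* N−1
  ensemble members asserting the pair; the best alignment is the argmax,
  ties breaking to the lowest index. An alignment with no pairs scores 0.
- The per-column confidence score is the same quantity restricted to one
  column's pairs; columns scoring below the threshold (default 0.93) or
  carrying no pair evidence (< 2 residues) are removed before tree
  building. This ensemble-agreement filter replaces guide-tree-resampling
  confidence scores: it needs no aligner re-runs, and the 0.93 default is
  kept as the conventional operating point.

Pair sets are computed internally as sorted integer codes so that
100-replicate runs on 40-sequence families stay fast; the public
`residue_pairs` returns the explicit pair set.

## Distances and neighbor joining

Protein distances are Poisson-corrected proportions of differing sites,
d = −ln(1 − p), with p ≥ 1 treated as an error (saturation). Gap handling
defaults to complete deletion (drop any column containing a gap or
non-standard residue); pairwise deletion is available by flag. NJ is the
standard Q-criterion agglomeration with negative branch-length estimates
clamped to zero; Q ties break toward the lexicographically smallest pair
of cluster labels (a cluster is labelled by its smallest member), making
the tree a pure function of the matrix. On additive matrices NJ recovers
the generating topology and branch lengths exactly (to 1e-9), which the
test suite checks on random trees of 5–12 taxa.

The simulator's substitution model (below) is matched to this correction,
so distance-based reconstruction error in the benchmarks reflects
sampling noise, not model misspecification.

## Parsimony

`fitch_score` is the vectorized Fitch dynamic program on the 20-letter
amino-acid alphabet (bitmask per column); gaps and ambiguous residues are
missing data (full state set), not a 21st state. It requires binary
trees; `sankoff_score`, a uniform-cost Sankoff DP that also handles
polytomies, serves as the independent oracle — the suite verifies
equality on hundreds of random (tree, column) pairs.

The maximum-parsimony search is a deterministic close-neighbor-
interchange hill-climb started from the NJ topology:

- only strict score decreases are accepted;
- equal-score neighbors join a bounded plateau (default 8 topologies)
  whose members are also expanded, so tied rearrangement paths are not
  dead ends;
- at convergence a *second* interchange is probed through the best
  non-improving first-level neighbors (margin 2 steps, width
  min(4·(n−3), 12)), the "close neighbor" part of CNI, catching shallow
  two-move traps.

Uninformative columns contribute a topology-independent constant
(distinct observed states − 1) and are excluded from the vectorized
scorer; candidate moves are rescored incrementally along the dirtied
root-bound path, stopping as soon as a node's state set comes out
unchanged. On random 6-taxon data the search matches the exhaustive
105-topology optimum in ≥ 95% of trials and can never beat it. All
co-optimal trees on the final plateau are returned.

## Bootstrap

Nonparametric column bootstrap (default n = 100): resample columns with
replacement, re-run the method (NJ per replicate; for MP, NJ start plus
CNI per replicate), and report per-bipartition support in percent. By
default supports map onto the full-data tree; a majority-rule consensus
of the replicates is available by flag, since published procedures vary
in which tree they annotate. Replicate resampling is driven by one seed;
identical seeds give identical supports.

## Combination and HGT calling

`combine_method_trees` keeps exactly the bipartitions present in every
input tree (≥ 2 trees over one leaf set) — the strongest reading of
"only branches supported by all methods" — collapsing everything else
into polytomies. Branch lengths are dropped (methods' lengths are not
commensurable); every retained edge carries the ordered support list
(ML, NJ, MP; `-` for a method without a value). A relaxed
`min_methods` mode (must exceed half the inputs, so the kept splits stay
compatible) supports sensitivity analysis. The operation is exactly the
split-set intersection, hence order-independent and idempotent.

Confirmation re-runs the screen on the combined tree, rooted by the
configured outgroup, else by carrying over the reference tree's root
bipartition (best-matching edge), else at the combined tree's own
constructed root. A candidate re-detected with the same host kingdom is
*confirmed*; one sitting in a collapsed polytomy that touches both its
kingdoms is *unresolved* (the consensus does not adjudicate it — reported
explicitly instead of being resolved by eye); anything else is
*rejected*.

Events are maximal clades consisting solely of confirmed leaves sharing
one (source, host) kingdom pair, with one extension: same-pair groups
hanging side by side from a single multifurcation count as one event,
because the collapsed consensus does not separate them and fragmenting
them would manufacture spurious extra events on noisy reconstructions.
Isolated confirmed leaves are singleton events; events with ≥ 5 members
(configurable) are flagged *ancient*, the multi-gene transfers drawn as
triangles in published family trees. Direction is reported as source
kingdom → host kingdom of the surrounding clade; no reconciliation-based
inference of the donor lineage is attempted.

## Synthetic families

The generator defines the study conditions used throughout the tests:

- **Tree**: uniform sequential pairwise joins within each kingdom (every
  kingdom initially monophyletic), then joins of the kingdom roots;
  exponential branch lengths with mean `edge_scale` = 0.08
  substitutions/site — moderate divergence for a protein family, deep
  enough that reconstruction is nontrivial, far from saturation.
- **Transfers**: `n_events` = 3 subtree-prune-regraft moves; a donor
  clade of 3–6 leaves is pruned from its kingdom and regrafted onto an
  internal edge strictly inside another kingdom's region, never nesting
  inside an earlier graft. The answer key records every moved leaf.
- **Sequences**: root drawn uniform over 20 amino acids; along an edge of
  length t each site substitutes with probability 1 − e^(−t) to a
  uniformly chosen different residue. Two leaves joined by a path with
  edge lengths t_i share a site with probability
  1/20 + (19/20)·Π λ(t_i), λ(t) = (20e^(−t) − 1)/19 — the closed form the
  simulator tests verify by simulation. The Poisson correction inverts
  this decay up to multiple hits (within 10% for the branch lengths
  used).
- **Ensembles**: the true alignment (the evolved site matrix; no indel
  process) plus perturbed copies. A perturbation covers a `rate` fraction
  of columns (default 0.1) with width-2 shift windows in which a random
  row subset slides one column across an inserted gap — destroying the
  windows' true residue pairs and asserting shifted false ones, the
  signature of real aligner error — while preserving every ungapped
  sequence. Pure pair-deletion perturbations would *raise* the
  perturbed alignment's MOS (its remaining pairs are all shared), so
  creating false pairs is essential for the ensemble to rank the true
  alignment first.
- **Defaults**: 2 kingdoms × 20 leaves, 400-aa sequences, 4-member
  ensembles, NJ + MP with 100 bootstrap replicates. One seed drives
  every stage; all outputs are byte-deterministic given the parameter
  set.

`evaluate_recovery` scores calls against the key at leaf level
(precision/recall over confirmed leaves; empty call sets have precision 1
by convention) and event level (greedy matching at Jaccard ≥ 0.5 member
overlap).

What passing these benchmarks shows: the screening rule is sound (zero
candidates on 200 kingdom-monophyletic trees) and complete (every planted
transfer recovered on noise-free trees), and the full
reconstruction-confirmation loop recovers planted transfers with
leaf-level precision and recall ≥ 0.9 under the default conditions. What
it does not show: robustness to indels and alignment length variation,
rate heterogeneity across sites and lineages, compositional bias,
incomplete or wrong taxonomies, duplication/loss paralogy, or the
taxon-sampling sparsity of real families — real screens should treat the
unresolved/rejected statuses and the fragment-length flags as first-class
outputs, not noise.

## Numerical and degenerate-input conventions

- Branch lengths: missing is "absent", never 0; absent lengths are an
  error where lengths are required (midpoint rooting, sequence
  evolution). Zero-length edges are legal.
- Newick: quoted labels, scientific-notation lengths and bracketed
  comments are accepted (comments dropped); duplicate leaf labels are
  rejected at parse time; parse errors name the offending position.
  Support annotations serialize as slash-separated values in the
  node-label position, `-` for a missing method.
- Bipartitions are canonically oriented (the block not containing the
  lexicographically smallest leaf); trivial splits are excluded
  everywhere; round trips preserve lengths to 1e-9.
- Ties: NJ ties break on cluster labels; MOS ties on ensemble index; the
  MP plateau keeps first-seen order. All pipeline stages are pure
  functions of inputs and seeds, and reports serialize with sorted keys
  and no timestamps, so identical runs are byte-identical.
- Problem sizes in the test suite (6-taxon exhaustive oracles, 5–12-taxon
  additive matrices, 20-replicate end-to-end runs at 2 × 20 leaves) were
  chosen so the full suite exercises every stage at depth in a few
  minutes on one CPU.

## Known limitations

- The screen's two-sided wrap test cannot, by construction, detect a
  transfer grafted exactly onto a kingdom clade's root edge (sister to
  the whole kingdom): such placements are indistinguishable from an
  outgroup arrangement without external rooting information.
- Maximum-likelihood inference is not reimplemented; an external ML tree
  participates only through the combiner.
- The CNI search is a local heuristic: it never beats exhaustive search
  and occasionally (≈ 3–5% of noisy small datasets) returns a slightly
  suboptimal score.
- Event counts on reconstructed trees depend on local topology: a single
  native leaf pulled into a transferred clade splits an event, and two
  adjacent transfers with identical kingdom pairs can merge; the
  event-count concordance reported by the acceptance script quantifies
  this at the default conditions.
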