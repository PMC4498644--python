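# Methods

This document records what each stage of the pipeline computes and the
choices that are not obvious from the code.

## Character matrix

The bundled fixture is a 33-taxon × 63-character morphological matrix
(states 0–3, unordered, equally weighted). Cell kinds:

- **observed** — a single state;
- **polymorphic** — a set of admissible states (coded `[01]`), charged no
  step when any member is compatible with the neighborhood;
- **missing** (`?`) and **inapplicable** (`-`) — both scored as fully
  unknown (the full state range of the character). They are distinguished
  in I/O and bookkeeping but are identical to the optimizer, matching
  standard parsimony practice for inapplicable codings.

Two analysis subsets are defined: Analysis 1 keeps the 31 ingroup species
plus *Acanthephyra purpurea*; Analysis 2 swaps that outgroup for *Alpheus
echiurophilus*. One matrix row is labelled *Rimicaris loihi* although the
species is treated in the text as *Opaepele loihi*; the parser accepts the
alias and normalizes to `Opaepele_loihi`.

## Fitch optimization

Tree length is the sum over characters of the minimum number of state
changes under Fitch's unordered-character dynamic program. The
implementation packs every character's state set into one 8-bit field of
a single Python integer, so a post-order pass intersects/unions all 63
characters at once; the number of empty intersections (the step count) is
extracted with a carry-borrow trick. Leaf sets come from the cell kinds
above. Correctness is tested against brute-force enumeration of all
ancestral assignments and against dendropy's Fitch pass.

## Tree search

- **Branch and bound** (implicit enumeration): taxa are added one at a
  time to every edge; a partial tree is pruned when its length plus an
  admissible future bound exceeds the best complete length. The bound
  counts, per character, states that appear in not-yet-placed taxa but not
  in the partial tree (each such state must cost at least one step). The
  bound is only applied to "clean" columns in which every cell is an
  observed singleton: a missing, inapplicable or polymorphic cell could
  absorb a new state for free, which would make the bound inadmissible.
  Guaranteed to return *all* minimum-length binary topologies; guarded to
  small taxon counts by default.
- **Heuristic search**: seeded random-addition starts followed by
  hill-climbing over NNI, SPR or TBR neighborhoods. TBR is evaluated
  without materializing neighbor trees: for each bisected edge both
  components are scored once with a directional dynamic program, and each
  reconnection is scored from precomputed root sets. All trees tied at the
  current optimum are saved (deduplicated by split set, capped by a
  configurable buffer), and the search continues until the optimal set is
  closed under the chosen rearrangement — the "TBR closure" used for MPT
  counts.

## Counting most-parsimonious trees

Distinct trees are compared as sets of non-trivial bipartitions. Because
equally parsimonious binary resolutions of an effectively unresolved node
would inflate the count, trees are also counted after **collapsing** every
branch whose *minimum* length over all most-parsimonious reconstructions
is zero (the standard TNT-style rule). The per-branch minimum/maximum
change counts come from a three-pass (down, up, combine) generalization of
Fitch's algorithm that yields, for every node, the states attainable in
some most-parsimonious reconstruction, and for every branch, the bracket
[min, max] of changes across reconstructions.

## Support

- **Strict consensus**: intersection of the split sets of the input trees.
- **Bootstrap**: characters resampled with replacement; each
  pseudoreplicate searched with a cheap profile (5 starts + SPR by
  default); a split's support is the percentage of replicates whose strict
  consensus contains it.
- **Bremer decay**: the saved-tree pool is expanded by TBR from the
  minimum-length trees, keeping everything within `margin` steps of the
  optimum (default 3) up to a tree cap (default 10000). A split's decay is
  the smallest length excess among pool trees lacking it; if no pool tree
  lacks it the value is censored and reported as ">margin". An exact
  exhaustive-enumeration mode cross-checks the pool method for ≤ 9 taxa.
- **Robust clades**: splits are projected onto the taxa shared by both
  analyses (the 31 ingroup species) and kept when present in both strict
  consensus trees with decay ≥ 3 (censored counts as passing) in both.

## Synapomorphies

For a named clade present in a tree, the stem branch is located under the
outgroup rooting and every character whose minimum change count on that
branch is positive is reported as an **unambiguous** stem change
(characters changing in only some reconstructions are flagged
**ambiguous**). The published synapomorphy lists are recovered as the
intersection of unambiguous stem changes over *every* MPT of both
analyses. Character indices are 0-based, matching the numbering of the
bundled character-definition table.

## Molecular distances

Alignments are trimmed to the span covered by the shortest sequence
(terminal gap columns removed), then uncorrected p-distances are computed
with pairwise deletion: sites with a gap or ambiguity code in either
sequence are excluded. Group comparisons report min/mean/max over all
cross-group pairs.

## Simulation

`simulate_tree` draws a Yule topology (leaf labels permuted so the shape
is exchangeable); branch lengths are either depth-normalized Yule times or
fixed. `simulate_characters` evolves k-state Mk characters using the exact
transition probability `P(same) = 1/k + (k-1)/k · exp(−k·r·t/(k−1))`, then
masks cells to missing/polymorphic at configured fractions.
`simulate_alignment` evolves Jukes–Cantor sequences (the k=4 special
case). Three independent seeded streams (tree, characters, sequences) make
every artifact reproducible from one seed. The simulator validates the
stack: bootstrap support is 100% on homoplasy-free matrices, topology
recovery exceeds 95% at low rate with many characters, and mean
p-distances match the closed form `E[p] = 3/4 (1 − e^{−4t/3})`.

## Known deviation

The Analysis 2 collapsed MPT count is 450 here versus 437 published; see
the README for the buffer-truncation analysis. All other headline numbers
reproduce exactly.
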