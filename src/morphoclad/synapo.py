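"""Ancestral-state reconstruction and synapomorphy extraction.

For every character the reconstruction works on per-state cost vectors (the
unordered-character special case of Sankoff's dynamic programme): ``D[v][s]``
is the minimum number of changes in the subtree below ``v`` given state ``s``
at ``v``; an up pass gives the complementary cost above each node.  From
these, each node's most-parsimonious state set (the states it takes in at
least one minimum-length reconstruction — the classical Fitch final sets on
binary trees) and each branch's minimum/maximum change status follow
directly, with no enumeration of reconstructions.

The same machinery yields minimum branch lengths, used to collapse branches
that can have zero changes in some most-parsimonious reconstruction — the
usual rule when counting distinct minimum-length trees.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .matrix import CharacterMatrix, subset_taxa
from .tree import Tree, TreeError, tree_from_splits

if TYPE_CHECKING:
    from .support import Bipartition

_INF = np.int64(10**6)


def _leaf_costs(matrix: CharacterMatrix) -> np.ndarray:
    """(n_taxa, n_characters, n_states) admissibility costs: 0 where the
    coded cell admits the state, a large constant otherwise."""
    S = max(c.max_state for c in matrix.characters) + 1
    n, k = matrix.n_taxa, matrix.n_characters
    C = np.full((n, k, S), _INF, dtype=np.int64)
    for i, row in enumerate(matrix.cells):
        for c, cell in enumerate(row):
            for s in cell.states:
                C[i, c, s] = 0
    return C


def _f(x: np.ndarray) -> np.ndarray:
    """One-edge propagation for unordered characters: stay at cost x, or
    change once from the cheapest state."""
    return np.minimum(x, x.min(axis=-1, keepdims=True) + 1)


class AncestralReconstruction:
    """Per-node, per-character most-parsimonious state sets for one tree."""

    def __init__(self, tree: Tree, matrix: CharacterMatrix,
                 outgroup: str | None = None):
        if set(tree.taxa) != set(matrix.taxa):
            raise TreeError("tree leaves do not match matrix taxa")
        if tuple(tree.taxa) != matrix.taxa:
            matrix = subset_taxa(matrix, tree.taxa)
        self.tree = tree
        self.matrix = matrix
        self.outgroup = outgroup
        n = len(tree.taxa)
        leafC = _leaf_costs(matrix)
        order, parent = tree.rooted_orientation(outgroup)
        self._order, self._parent = order, parent
        adj = tree.adj
        D: dict[int, np.ndarray] = {}
        for v in reversed(order):
            if v < n:
                D[v] = leafC[v]
                continue
            kids = [w for w in adj[v] if w != parent[v]]
            D[v] = sum(_f(D[w]) for w in kids)
        root = order[0]
        self.char_lengths = D[root].min(axis=-1)
        self.total_length = int(self.char_lengths.sum())
        # G[v]: cost of everything above the edge (parent(v), v), given the
        # state of parent(v); G at the root's children uses only siblings.
        G: dict[int, np.ndarray] = {}
        U: dict[int, np.ndarray] = {root: np.zeros_like(D[root])}
        for v in order:
            kids = [w for w in adj[v] if w != parent[v]]
            if not kids:
                continue
            fk = {w: _f(D[w]) for w in kids}
            tot = U[v] + sum(fk.values())
            for w in kids:
                G[w] = tot - fk[w]
                U[w] = _f(G[w])
        self._D, self._G, self._U = D, G, U

    def _forced(self, v: int) -> np.ndarray:
        return self._D[v] + self._U[v]

    def state_sets(self, node: int) -> tuple[frozenset[int], ...]:
        """Per character, the set of states *node* takes in at least one
        most-parsimonious reconstruction."""
        F = self._forced(node)
        Lc = self.char_lengths
        return tuple(frozenset(np.flatnonzero(F[c] == Lc[c]).tolist())
                     for c in range(self.matrix.n_characters))

    def branch_change_profile(self, child: int):
        """Per character: minimum and maximum number of changes (0 or 1) on
        the branch above *child* over all most-parsimonious reconstructions."""
        p = self._parent[child]
        if p is None:
            raise TreeError("the root has no branch above it")
        G, D, Lc = self._G[child], self._D[child], self.char_lengths
        no_change = (G + D).min(axis=-1)  # parent and child share a state
        # cheapest with a forced change: distinct states on the two ends
        S = G.shape[-1]
        ii, jj = np.nonzero(~np.eye(S, dtype=bool))
        with_change = (G[:, ii] + 1 + D[:, jj]).min(axis=-1)
        min_changes = (no_change > Lc).astype(int)
        max_changes = (with_change == Lc).astype(int)
        return min_changes, max_changes

    def min_branch_length(self, child: int) -> int:
        """Summed minimum changes on the branch above *child*."""
        return int(self.branch_change_profile(child)[0].sum())


@dataclass(frozen=True)
class CharacterChange:
    """One inferred change on a branch.  ``ambiguity`` is "unambiguous" when
    every most-parsimonious reconstruction changes on the branch (the parent
    and child state sets are then disjoint), "ambiguous" when only some do."""

    character_index: int
    branch: tuple[frozenset[str], frozenset[str]]
    from_states: frozenset[int]
    to_states: frozenset[int]
    ambiguity: str

    def __post_init__(self):
        if self.ambiguity not in ("unambiguous", "ambiguous"):
            raise ValueError("bad ambiguity flag")
        if self.ambiguity == "unambiguous" and self.from_states & self.to_states:
            raise ValueError("an unavoidable change cannot share end states")


def ancestral_state_sets(tree: Tree, matrix: CharacterMatrix,
                         outgroup: str | None = None) -> AncestralReconstruction:
    """Most-parsimonious state sets at every node (Fitch final sets)."""
    return AncestralReconstruction(tree, matrix, outgroup)


def stem_synapomorphies(tree: Tree, matrix: CharacterMatrix,
                        clade: "Bipartition", outgroup: str | None = None,
                        include_ambiguous: bool = True
                        ) -> list[CharacterChange]:
    """Character changes on the stem branch of *clade* in *tree*.

    Unambiguous changes (present in every most-parsimonious reconstruction)
    are always reported; ambiguous candidates (present in some) are included
    when ``include_ambiguous`` and flagged.
    """
    rec = AncestralReconstruction(tree, matrix, outgroup)
    return stem_synapomorphies_from(rec, clade, include_ambiguous)


def stem_synapomorphies_from(rec: AncestralReconstruction,
                             clade: "Bipartition",
                             include_ambiguous: bool = True
                             ) -> list[CharacterChange]:
    """Stem changes for one clade from an existing reconstruction (lets one
    reconstruction per tree serve several clades)."""
    tree, matrix = rec.tree, rec.matrix
    n = len(tree.taxa)
    want = frozenset(clade.side)
    below, parent = {}, rec._parent
    for v in reversed(rec._order):
        below[v] = (frozenset({tree.taxa[v]}) if v < n
                    else frozenset().union(*[below[w] for w in tree.adj[v]
                                             if w != parent[v]]))
    comp = frozenset(clade.universe - clade.side)
    stem = next((v for v in below
                 if below[v] in (want, comp) and parent[v] is not None), None)
    if stem is None:
        raise TreeError("clade not present in the tree under this rooting")
    minc, maxc = rec.branch_change_profile(stem)
    child_sets = rec.state_sets(stem)
    parent_sets = rec.state_sets(parent[stem])
    branch = (below[parent[stem]], below[stem])
    out = []
    for c in range(matrix.n_characters):
        if minc[c]:
            out.append(CharacterChange(c, branch, parent_sets[c],
                                       child_sets[c], "unambiguous"))
        elif maxc[c] and include_ambiguous:
            out.append(CharacterChange(c, branch, parent_sets[c],
                                       child_sets[c], "ambiguous"))
    return out


def common_stem_synapomorphies(trees: Sequence[Tree], matrix: CharacterMatrix,
                               clade: "Bipartition",
                               outgroup: str | None = None) -> set[int]:
    """Characters changing unambiguously on the clade's stem in EVERY tree
    (the paper-style "synapomorphies common to all most-parsimonious
    trees")."""
    common: set[int] | None = None
    for t in trees:
        rec = AncestralReconstruction(t, matrix, outgroup)
        got = {c.character_index
               for c in stem_synapomorphies_from(rec, clade, False)}
        common = got if common is None else common & got
        if not common:
            break
    return common or set()


def _collapsed_splits(tree: Tree, matrix: CharacterMatrix) -> frozenset[int]:
    """The informative splits surviving zero-length-branch collapsing."""
    rec = AncestralReconstruction(tree, matrix)
    n = len(tree.taxa)
    full = (1 << n) - 1
    below: dict[int, int] = {}
    for v in reversed(rec._order):
        below[v] = (1 << v) if v < n else 0
        for w in tree.adj[v]:
            if rec._parent.get(w) == v:
                below[v] |= below[w]
    kept = set()
    Lc = rec.char_lengths
    for v, p in rec._parent.items():
        if p is None:
            continue
        m = below[v]
        mm = m if not (m & 1) else full ^ m
        if mm.bit_count() < 2 or (full ^ mm).bit_count() < 2:
            continue
        no_change = ((rec._G[v] + rec._D[v]).min(axis=-1) > Lc)
        if no_change.any():
            kept.add(mm)
    return frozenset(kept)


def collapse_zero_length_branches(tree: Tree, matrix: CharacterMatrix) -> Tree:
    """Collapse every branch whose minimum length over all most-parsimonious
    reconstructions is zero (the usual rule before counting distinct
    minimum-length trees)."""
    return tree_from_splits(tree.taxa, _collapsed_splits(tree, matrix))


def count_collapsed(trees: Sequence[Tree], matrix: CharacterMatrix) -> int:
    """Number of distinct topologies after zero-length-branch collapsing."""
    return len({_collapsed_splits(t, matrix) for t in trees})


def synapomorphy_table(changes: Sequence[CharacterChange],
                       matrix: CharacterMatrix, clade_name: str = "") -> str:
    """Changes as TSV: clade, character index, label, from→to, ambiguity."""
    lines = ["clade\tcharacter\tlabel\tfrom\tto\tambiguity"]
    for ch in changes:
        label = matrix.characters[ch.character_index].label
        frm = ",".join(map(str, sorted(ch.from_states)))
        to = ",".join(map(str, sorted(ch.to_states)))
        lines.append(f"{clade_name}\t{ch.character_index}\t{label}\t"
                     f"{frm}\t{to}\t{ch.ambiguity}")
    return "\n".join(lines) + "\n"
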