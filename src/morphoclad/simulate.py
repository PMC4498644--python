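"""Synthetic data with known ground truth: Yule trees, Mk-model discrete
character matrices (with configurable missingness and polymorphism), and
Jukes–Cantor nucleotide alignments.

One root seed fans out deterministically to three independent child streams
(tree / characters / alignment) via ``numpy.random.SeedSequence.spawn``, so
drawing from one generator never perturbs the others.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .matrix import CellCoding, CharacterDefinition, CharacterMatrix
from .seqdist import SequenceAlignment
from .tree import Tree

_TREE_STREAM, _CHAR_STREAM, _SEQ_STREAM = 0, 1, 2


@dataclass
class SimulationConfig:
    n_taxa: int = 12
    n_characters: int = 63
    n_states: int = 2
    substitution_rate: float = 0.3
    missing_fraction: float = 0.0
    polymorphic_fraction: float = 0.0
    seed: int = 0
    seq_length: int = 500
    branch_length_model: Literal["yule_unit", "fixed"] = "yule_unit"

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if not 2 <= self.n_states <= 4:
            raise ValueError("n_states must be 2-4")
        for frac in (self.missing_fraction, self.polymorphic_fraction):
            if not 0 <= frac < 1:
                raise ValueError("fractions must lie in [0, 1)")
        if self.missing_fraction + self.polymorphic_fraction >= 1:
            raise ValueError("masking fractions must sum to < 1")
        if self.seq_length < 1 or self.substitution_rate < 0:
            raise ValueError("invalid simulation parameters")


@dataclass
class SimulatedTree:
    """An unrooted topology with branch lengths (in tree-depth units)."""

    tree: Tree
    lengths: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self):
        edges = set(self.tree.edges())
        if set(self.lengths) != edges:
            raise ValueError("branch lengths do not cover the tree's edges")

    def newick(self) -> str:
        n = len(self.tree.taxa)
        order, parent = self.tree.rooted_orientation()

        def rec(v):
            e = None if parent[v] is None else (min(v, parent[v]), max(v, parent[v]))
            blen = "" if e is None else f":{self.lengths[e]:.6f}"
            if v < n:
                return self.tree.taxa[v] + blen
            kids = [w for w in self.tree.adj[v] if w != parent[v]]
            return "(" + ",".join(rec(w) for w in kids) + ")" + blen

        return rec(order[0]) + ";"


def _streams(config: SimulationConfig) -> list[np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(3)
    return [np.random.Generator(np.random.PCG64(c)) for c in children]


def simulate_tree(config: SimulationConfig) -> SimulatedTree:
    """A seeded Yule-process topology.

    Lineages split uniformly at random; waiting times are exponential with
    rate = number of extant lineages (standard unit-rate Yule), or every
    branch gets length 1 under the ``fixed`` model.
    """
    rng = _streams(config)[_TREE_STREAM]
    n = config.n_taxa
    taxa = tuple(f"taxon_{i:02d}" for i in range(n))
    # grow a rooted binary tree; node ids: leaves 0..n-1 assigned at the end
    next_id = n  # internal ids
    root = next_id
    next_id += 1
    # active lineages represented by (pending-subtree token)
    children: dict[int, list[int]] = {root: []}
    parent_of: dict[int, int] = {}
    active = []
    for _ in range(2):
        node = next_id
        next_id += 1
        children[root].append(node)
        children[node] = []
        parent_of[node] = root
        active.append(node)
    birth: dict[int, float] = {x: 0.0 for x in active}
    branch_len: dict[int, float] = {}
    t = 0.0
    while len(active) < n:
        t += float(rng.exponential(1.0 / len(active)))
        idx = int(rng.integers(len(active)))
        split = active.pop(idx)
        branch_len[split] = t - birth[split]
        children[split] = []
        for _ in range(2):
            node = next_id
            next_id += 1
            children[split].append(node)
            children[node] = []
            parent_of[node] = split
            birth[node] = t
            active.append(node)
    t_end = t + float(rng.exponential(1.0 / len(active)))
    # leaf labels are an exchangeable random permutation of the lineages
    perm = rng.permutation(n)
    leaf_map = {node: int(perm[i]) for i, node in enumerate(sorted(active))}
    # build adjacency with final ids: leaves 0..n-1, internals n..2n-2
    internal_ids = sorted(x for x in children if children[x])
    rename = {x: n + i for i, x in enumerate(internal_ids)}
    rename.update(leaf_map)
    adj: dict[int, set[int]] = {}
    elen: dict[tuple[int, int], float] = {}
    for x, kids in children.items():
        for k in kids:
            a, b = rename[x], rename[k]
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
            L = branch_len[k] if children[k] else t_end - birth[k]
            elen[(min(a, b), max(a, b))] = L
    # suppress the degree-2 root to make the tree unrooted
    r = rename[root]
    a, b = adj[r]
    adj[a].discard(r)
    adj[b].discard(r)
    adj[a].add(b)
    adj[b].add(a)
    del adj[r]
    ra = elen.pop((min(r, a), max(r, a)))
    rb = elen.pop((min(r, b), max(r, b)))
    elen[(min(a, b), max(a, b))] = ra + rb
    if config.branch_length_model == "fixed":
        elen = {e: 1.0 for e in elen}
    else:
        depth = t_end if t_end > 0 else 1.0
        elen = {e: L / depth for e, L in elen.items()}  # unit tree depth
    return SimulatedTree(Tree(taxa, adj), elen)


def _evolve_states(sim: SimulatedTree, k: int, n_sites: int, rate: float,
                   rng: np.random.Generator) -> np.ndarray:
    """(n_taxa, n_sites) states under a k-state symmetric Markov process from
    a uniform root state (simulated from an arbitrary node — valid because
    the process is reversible with uniform stationary distribution)."""
    tree = sim.tree
    n = len(tree.taxa)
    order, parent = tree.rooted_orientation()
    states: dict[int, np.ndarray] = {
        order[0]: rng.integers(k, size=n_sites).astype(np.int64)}
    out = np.zeros((n, n_sites), dtype=np.int64)
    for v in order:
        if parent[v] is not None:
            e = (min(v, parent[v]), max(v, parent[v]))
            t = sim.lengths[e] * rate
            p_same = 1.0 / k + (k - 1.0) / k * np.exp(-k * t / (k - 1.0))
            src = states[parent[v]]
            change = rng.random(n_sites) >= p_same
            shift = rng.integers(1, k, size=n_sites)
            states[v] = np.where(change, (src + shift) % k, src)
        if v < n:
            out[v] = states[v]
    return out


def simulate_characters(sim: SimulatedTree,
                        config: SimulationConfig) -> CharacterMatrix:
    """Mk-model characters on the tree, then seeded masking: a masked cell
    becomes missing (`?`), a widened cell becomes a two-state polymorphism
    containing the true state."""
    rng = _streams(config)[_CHAR_STREAM]
    k = config.n_states
    data = _evolve_states(sim, k, config.n_characters,
                          config.substitution_rate, rng)
    n, m = data.shape
    u = rng.random((n, m))
    taxa = sim.tree.taxa
    chars = tuple(
        CharacterDefinition(c, f"char_{c:02d}",
                            tuple(str(s) for s in range(k)))
        for c in range(m))
    full = frozenset(range(k))
    cells = []
    for i in range(n):
        row = []
        for c in range(m):
            s = int(data[i, c])
            if u[i, c] < config.missing_fraction:
                row.append(CellCoding("missing", full))
            elif u[i, c] < config.missing_fraction + config.polymorphic_fraction and k >= 2:
                other = (s + 1 + int(rng.integers(k - 1))) % k
                row.append(CellCoding("polymorphic", frozenset({s, other})))
            else:
                row.append(CellCoding("observed", frozenset({s})))
        cells.append(tuple(row))
    return CharacterMatrix(taxa, chars, tuple(cells))


def simulate_alignment(sim: SimulatedTree,
                       config: SimulationConfig) -> SequenceAlignment:
    """Jukes–Cantor nucleotide evolution along the tree, seeded."""
    rng = _streams(config)[_SEQ_STREAM]
    data = _evolve_states(sim, 4, config.seq_length,
                          config.substitution_rate, rng)
    bases = np.array(list("ACGT"))
    return SequenceAlignment(
        (sim.tree.taxa[i], "".join(bases[data[i]])) for i in range(len(data)))
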