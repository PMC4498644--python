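"""Shared test utilities: random data, independent oracles.

Everything here is deliberately written as straight-line reference code,
independent of the package's optimized kernels, so it can serve as an oracle.
"""
from __future__ import annotations

import itertools
import random

from morphoclad.matrix import (CellCoding, CharacterDefinition,
                               CharacterMatrix)
from morphoclad.tree import Tree, all_topologies


def random_matrix(rng: random.Random, n_taxa: int, n_chars: int,
                  max_state: int = 1, p_missing: float = 0.0,
                  p_inapplicable: float = 0.0,
                  p_polymorphic: float = 0.0) -> CharacterMatrix:
    taxa = tuple(f"t{i}" for i in range(n_taxa))
    chars = tuple(
        CharacterDefinition(c, f"char_{c}",
                            tuple(str(s) for s in range(max_state + 1)))
        for c in range(n_chars))
    full = frozenset(range(max_state + 1))
    cells = []
    for _ in range(n_taxa):
        row = []
        for _c in range(n_chars):
            u = rng.random()
            if u < p_missing:
                row.append(CellCoding("missing", full))
            elif u < p_missing + p_inapplicable:
                row.append(CellCoding("inapplicable", full))
            elif u < p_missing + p_inapplicable + p_polymorphic and max_state >= 1:
                s = rng.randrange(max_state + 1)
                t = (s + 1 + rng.randrange(max_state)) % (max_state + 1)
                row.append(CellCoding("polymorphic", frozenset({s, t})))
            else:
                row.append(CellCoding(
                    "observed", frozenset({rng.randrange(max_state + 1)})))
        cells.append(tuple(row))
    return CharacterMatrix(taxa, chars, tuple(cells))


def dendropy_fitch_length(tree: Tree, matrix: CharacterMatrix) -> int:
    """Independent Fitch length via dendropy (no polymorphic cells)."""
    import dendropy
    from dendropy.model.parsimony import fitch_down_pass
    tns = dendropy.TaxonNamespace(list(matrix.taxa))
    dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    rows = []
    for name, row in zip(matrix.taxa, matrix.cells):
        rows.append(f">{name}\n" + "".join(c.token() for c in row))
    chars = dendropy.StandardCharacterMatrix.get(
        data="\n".join(rows) + "\n", schema="fasta", taxon_namespace=tns)
    tsm = chars.taxon_state_sets_map(gaps_as_missing=True)
    dt.encode_bipartitions()
    return fitch_down_pass(dt.postorder_node_iter(),
                           taxon_state_sets_map=tsm)


def exhaustive_minimum(matrix: CharacterMatrix):
    """(min length, set of optimal split-keys) over every binary topology."""
    from morphoclad.fitch import Encoding, tree_length
    enc = Encoding(matrix)
    best, keys = None, set()
    for t in all_topologies(matrix.taxa):
        L = tree_length(t, enc)
        if best is None or L < best:
            best, keys = L, {t.splits()}
        elif L == best:
            keys.add(t.splits())
    return best, keys


def brute_force_character(tree: Tree, matrix: CharacterMatrix, c: int):
    """Exhaustive most-parsimonious reconstructions of character *c*.

    Returns (min_length, node -> optimal state set,
    edge -> (min changes, max changes) over optimal assignments).
    """
    n = len(tree.taxa)
    k = matrix.characters[c].max_state + 1
    internal = sorted(x for x in tree.adj if x >= n)
    edges = tree.edges()
    leaf_opts = [sorted(matrix.cells[i][c].states) for i in range(n)]
    nodes = list(range(n)) + internal
    opts = [leaf_opts[x] if x < n else list(range(k)) for x in nodes]
    best = None
    optimal = []
    for assign in itertools.product(*opts):
        a = dict(zip(nodes, assign))
        steps = sum(1 for u, v in edges if a[u] != a[v])
        if best is None or steps < best:
            best, optimal = steps, [a]
        elif steps == best:
            optimal.append(a)
    sets = {x: frozenset(a[x] for a in optimal) for x in nodes}
    prof = {}
    for u, v in edges:
        ch = [1 if a[u] != a[v] else 0 for a in optimal]
        prof[(u, v)] = (min(ch), max(ch))
    return best, sets, prof


def brute_force_spr_neighbors(tree: Tree) -> set[frozenset[int]]:
    """Split-key sets of all one-move prune+regraft neighbours, computed by
    direct adjacency surgery (independent of the package's sweep machinery)."""
    n = len(tree.taxa)
    out: set[frozenset[int]] = set()
    base = tree.splits()
    for pu, pv in list(tree.edges()):
        # prune the component containing pu (cut edge pu-pv), regraft it onto
        # every edge of the pv component, and vice versa
        for root, anchor in ((pu, pv), (pv, pu)):
            adj = {x: set(s) for x, s in tree.adj.items()}
            adj[root].discard(anchor)
            adj[anchor].discard(root)
            # nodes of the pruned component
            comp = {root}
            stack = [root]
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if y not in comp:
                        comp.add(y)
                        stack.append(y)
            rest = set(adj) - comp
            if len(rest) < 2:
                continue
            # suppress the degree-2 anchor in the remaining component
            adj2 = {x: set(s) for x, s in adj.items()}
            if anchor in adj2 and len(adj2[anchor]) == 2 and anchor >= n:
                a, b = adj2[anchor]
                adj2[a].discard(anchor)
                adj2[b].discard(anchor)
                adj2[a].add(b)
                adj2[b].add(a)
                del adj2[anchor]
                rest.discard(anchor)
            rest_edges = [(u, v) for u in rest for v in adj2.get(u, ())
                          if u < v and v in rest]
            new_id = max(adj2) + 1
            for a, b in rest_edges:
                adj3 = {x: set(s) for x, s in adj2.items()}
                adj3[a].discard(b)
                adj3[b].discard(a)
                adj3[new_id] = {a, b, root}
                adj3[a].add(new_id)
                adj3[b].add(new_id)
                adj3[root] = set(adj3.get(root, set())) | {new_id}
                t2 = Tree(tree.taxa, adj3)
                t2._suppress_degree_two()
                k = t2.splits()
                if k != base:
                    out.add(k)
    return out


def congruent_matrix(tree: Tree, copies: int = 1) -> CharacterMatrix:
    """A homoplasy-free binary matrix: one character (repeated *copies*
    times) marking each informative split of *tree*."""
    n = len(tree.taxa)
    chars = []
    cols = []
    for m in sorted(tree.splits()):
        col = [1 if (m >> i) & 1 else 0 for i in range(n)]
        for _ in range(copies):
            cols.append(col)
    chars = tuple(CharacterDefinition(c, f"char_{c}", ("0", "1"))
                  for c in range(len(cols)))
    cells = tuple(
        tuple(CellCoding("observed", frozenset({cols[c][i]}))
              for c in range(len(cols)))
        for i in range(n))
    return CharacterMatrix(tree.taxa, chars, cells)


def path_length(sim, leaf_a: int, leaf_b: int) -> float:
    """Sum of branch lengths on the path between two leaves of a
    SimulatedTree."""
    tree = sim.tree
    parent = {leaf_a: None}
    stack = [leaf_a]
    while stack:
        u = stack.pop()
        for v in tree.adj[u]:
            if v not in parent:
                parent[v] = u
                stack.append(v)
    total = 0.0
    x = leaf_b
    while parent[x] is not None:
        p = parent[x]
        total += sim.lengths[(min(x, p), max(x, p))]
        x = p
    return total
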