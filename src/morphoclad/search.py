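"""Minimum-length tree search.

Two engines are provided: an exact branch-and-bound (stepwise taxon addition
with an admissible per-character bound, guaranteeing ALL minimum-length
topologies) for small taxon sets, and a heuristic engine (seeded
random-addition starts followed by NNI/SPR/TBR hill-climbing, then closure of
the optimal set under the chosen rearrangement) for full-size matrices.

The TBR machinery scores whole neighbourhoods incrementally: bisecting an
edge splits the tree into two components whose lengths are fixed, and the
length of any reconnection is their sum plus the join cost of the two
directional Fitch state sets at the reconnection edges.  A full TBR sweep of
a 32-taxon tree therefore costs tens of thousands of cheap set joins rather
than full rescorings.
"""
from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

from .fitch import Encoding
from .matrix import CharacterMatrix
from .tree import Tree, TreeError

Swap = Literal["nni", "spr", "tbr"]


@dataclass
class SearchConfig:
    """Knobs of the heuristic engine.

    ``keep_margin`` is the length excess (in steps) up to which suboptimal
    trees encountered during closure are retained, bounded by
    ``max_saved_trees`` — the profile used for decay-index runs is
    ``keep_margin=3, max_saved_trees=10000``.
    """

    mode: Literal["exact", "heuristic"] = "heuristic"
    n_starts: int = 100
    swap: Swap = "tbr"
    seed: int = 0
    keep_margin: int = 0
    max_saved_trees: int = 10000

    def __post_init__(self):
        if self.n_starts < 1 or self.keep_margin < 0 or self.max_saved_trees < 1:
            raise ValueError("invalid search configuration")


class TreeSet:
    """Trees deduplicated by bipartition set, kept within a length margin."""

    def __init__(self, keep_margin: int = 0, max_saved_trees: int = 10**9):
        self.keep_margin = keep_margin
        self.max_saved_trees = max_saved_trees
        self.best_length: int | None = None
        self._trees: dict[frozenset[int], tuple[Tree, int]] = {}

    def add(self, tree: Tree, length: int, key: frozenset[int] | None = None) -> bool:
        if self.best_length is not None and length > self.best_length + self.keep_margin:
            return False
        if key is None:
            key = tree.canonical_key()
        if key in self._trees:
            return False
        if self.best_length is None or length < self.best_length:
            self.best_length = length
            cut = length + self.keep_margin
            self._trees = {k: tl for k, tl in self._trees.items() if tl[1] <= cut}
        if len(self._trees) >= self.max_saved_trees:
            return False
        self._trees[key] = (tree, length)
        return True

    def __len__(self) -> int:
        return len(self._trees)

    def __contains__(self, key: frozenset[int]) -> bool:
        return key in self._trees

    @property
    def trees(self) -> list[Tree]:
        return [t for t, _ in self._trees.values()]

    def items(self) -> list[tuple[Tree, int]]:
        return list(self._trees.values())

    def optimal_trees(self) -> list[Tree]:
        return [t for t, L in self._trees.values() if L == self.best_length]


def canonical_key(tree: Tree) -> str:
    """Rooting- and rotation-invariant topology identity: the sorted
    bipartition masks, hex-encoded.  Equal iff the split sets are equal."""
    return ",".join(format(m, "x") for m in sorted(tree.canonical_key()))


# ---------------------------------------------------------------------------
# bisection machinery
# ---------------------------------------------------------------------------

class _Component:
    """One side of a bisected tree, suppressed and rooted for directional
    Fitch sets.  ``cands`` lists (edge, root_set, below_mask) per candidate
    reconnection edge; a single-leaf component has one pseudo-edge."""

    __slots__ = ("length", "cands", "leaf_mask", "junction")

    def __init__(self, length, cands, leaf_mask, junction):
        self.length = length
        self.cands = cands
        self.leaf_mask = leaf_mask
        self.junction = junction


def _component(adj: dict[int, set[int]], start: int, cut: tuple[int, int],
               enc: Encoding, n: int) -> _Component:
    bu, bv = cut
    comp: dict[int, list[int]] = {}
    stack = [start]
    seen = {start}
    while stack:
        u = stack.pop()
        nbs = [x for x in adj[u]
               if not ((u == bu and x == bv) or (u == bv and x == bu))]
        comp[u] = nbs
        for x in nbs:
            if x not in seen:
                seen.add(x)
                stack.append(x)
    cut_end = bu if bu in comp else bv
    junction = None
    if not comp[cut_end]:  # singleton leaf
        return _Component(0, [((cut_end, cut_end), enc.leaf_sets[cut_end],
                               1 << cut_end)],
                          1 << cut_end, (cut_end, cut_end))
    if len(comp[cut_end]) == 2:  # suppress the degree-2 cut endpoint
        a, b = comp[cut_end]
        comp[a] = [x if x != cut_end else b for x in comp[a]]
        comp[b] = [x if x != cut_end else a for x in comp[b]]
        del comp[cut_end]
        junction = (min(a, b), max(a, b))
    combine = enc.combine
    leaf_sets = enc.leaf_sets
    if len(comp) == 2:
        a, b = comp
        s, st = combine(leaf_sets[a], leaf_sets[b])
        mask = (1 << a) | (1 << b)
        return _Component(st, [((min(a, b), max(a, b)), s, 1 << min(a, b))],
                          mask, junction)
    root = next(x for x in comp if len(comp[x]) > 1)
    parent: dict[int, int | None] = {root: None}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for v in comp[u]:
            if v != parent[u]:
                parent[v] = u
                order.append(v)
                stack.append(v)
    D: dict[int, int] = {}
    below: dict[int, int] = {}
    total = 0
    for u in reversed(order):
        if len(comp[u]) == 1:
            D[u] = leaf_sets[u]
            below[u] = 1 << u
            continue
        kids = [v for v in comp[u] if v != parent[u]]
        s = D[kids[0]]
        m = below[kids[0]]
        for v in kids[1:]:
            s, st = combine(s, D[v])
            total += st
            m |= below[v]
        if u < n:
            m |= 1 << u
        D[u] = s
        below[u] = m
    U: dict[int, int] = {}
    for u in order:
        kids = [v for v in comp[u] if v != parent[u]]
        for v in kids:
            s = U[u] if parent[u] is not None else None
            if u < n and parent[u] is None:  # leaf root (cannot happen; guard)
                s = leaf_sets[u]
            for w in kids:
                if w is not v:
                    s = D[w] if s is None else combine(s, D[w])[0]
            U[v] = s
    cands = []
    leaf_mask = below[root]
    for v, p in parent.items():
        if p is None:
            continue
        s, _ = combine(D[v], U[v])
        cands.append(((min(v, p), max(v, p)), s, below[v]))
    return _Component(total, cands, leaf_mask, junction)


def _apply_tbr(tree: Tree, move) -> Tree:
    """Materialize a bisect-and-reconnect move as a new Tree."""
    (u, v), ex, ey = move
    n = len(tree.taxa)
    adj = {k: set(s) for k, s in tree.adj.items()}
    adj[u].discard(v)
    adj[v].discard(u)

    def detach(node):
        if node < n or len(adj[node]) != 2:
            return None
        a, b = adj[node]
        adj[a].discard(node)
        adj[b].discard(node)
        adj[a].add(b)
        adj[b].add(a)
        del adj[node]
        return node

    free = [x for x in (detach(u), detach(v)) if x is not None]

    def attach(edge):
        a, b = edge
        if a == b:  # singleton leaf side
            return a
        node = free.pop() if free else max(adj) + 1
        adj[a].discard(b)
        adj[b].discard(a)
        adj[node] = {a, b}
        adj[a].add(node)
        adj[b].add(node)
        return node

    na = attach(ex)
    nb = attach(ey)
    adj[na].add(nb)
    adj[nb].add(na)
    return Tree(tree.taxa, adj)


def _neighbor_splits(cx: _Component, bx: int, cy: _Component, by: int,
                     n: int) -> frozenset[int]:
    """Bipartition set of the reconnected tree, without materializing it.

    ``bx``/``by`` are the below-masks of the chosen reconnection edges.
    """
    full = (1 << n) - 1
    out = set()

    def side(comp: _Component, bsel: int):
        mx = comp.leaf_mask
        for _, _, b in comp.cands:
            if b == bsel:
                masks = (b, mx ^ b)
            elif bsel & b == bsel:  # junction inside this subtree
                masks = (mx ^ b,)
            else:
                masks = (b,)
            for m in masks:
                if m & 1:
                    m = full ^ m
                if m.bit_count() >= 2 and (full ^ m).bit_count() >= 2:
                    out.add(m)

    side(cx, bx)
    side(cy, by)
    m = cx.leaf_mask
    if m & 1:
        m = full ^ m
    if m.bit_count() >= 2 and (full ^ m).bit_count() >= 2:
        out.add(m)
    return frozenset(out)


def _sweep(tree: Tree, enc: Encoding, swap: Swap) -> Iterator[tuple[int, tuple, _Component, int, _Component, int]]:
    """Yield (length, move, cx, below_x, cy, below_y) for every distinct
    bisect-and-reconnect neighbour under the given rearrangement family."""
    n = len(tree.taxa)
    adj = tree.adj
    join = enc.join_steps
    for e in tree.edges():
        u, v = e
        cx = _component(adj, u, e, enc, n)
        cy = _component(adj, v, e, enc, n)
        base = cx.length + cy.length
        if swap == "tbr":
            for ex, rx, bx in cx.cands:
                for ey, ry, by in cy.cands:
                    yield base + join(rx, ry), (e, ex, ey), cx, bx, cy, by
        else:  # spr: one side keeps its original junction
            for fixed, movit in ((cx, cy), (cy, cx)):
                jedge = fixed.junction or fixed.cands[0][0]
                sel = [c for c in fixed.cands if c[0] == jedge]
                if not sel:
                    continue
                exf, rxf, bxf = sel[0]
                for ey, ry, by in movit.cands:
                    if fixed is cx:
                        yield (base + join(rxf, ry), (e, exf, ey),
                               cx, bxf, cy, by)
                    else:
                        yield (base + join(ry, rxf), (e, ey, exf),
                               cx, by, cy, bxf)


def enumerate_rearrangements(tree: Tree, kind: Swap,
                             matrix: CharacterMatrix | None = None
                             ) -> Iterator[Tree]:
    """Stream the distinct neighbour topologies of *tree* (original excluded),
    deduplicated by bipartition set.  NNI is a subset of SPR, SPR of TBR."""
    if len(tree.taxa) < 4:
        raise TreeError("rearrangements need at least 4 taxa")
    if not tree.is_binary():
        raise TreeError("rearrangements are defined on binary trees")
    if kind == "nni":
        yield from _enumerate_nni(tree)
        return
    enc = _dummy_encoding(tree) if matrix is None else Encoding(matrix)
    seen = {tree.canonical_key()}
    for _L, move, *_ in _sweep(tree, enc, kind):
        t2 = _apply_tbr(tree, move)
        k = t2.canonical_key()
        if k not in seen:
            seen.add(k)
            yield t2


def _enumerate_nni(tree: Tree) -> Iterator[Tree]:
    n = len(tree.taxa)
    seen = {tree.canonical_key()}
    for u, v in tree.edges():
        if u < n or v < n:
            continue  # internal edges only
        us = [x for x in tree.adj[u] if x != v]
        vs = [x for x in tree.adj[v] if x != u]
        for b in vs:
            a = us[1]
            adj = {k: set(s) for k, s in tree.adj.items()}
            adj[u].discard(a); adj[a].discard(u)
            adj[v].discard(b); adj[b].discard(v)
            adj[u].add(b); adj[b].add(u)
            adj[v].add(a); adj[a].add(v)
            t2 = Tree(tree.taxa, adj)
            k = t2.canonical_key()
            if k not in seen:
                seen.add(k)
                yield t2


def _dummy_encoding(tree: Tree) -> Encoding:
    from .matrix import CharacterDefinition, CellCoding, CharacterMatrix as CM
    chars = (CharacterDefinition(0, "dummy", ("0", "1")),)
    cells = tuple((CellCoding("observed", frozenset({0})),) for _ in tree.taxa)
    return Encoding(CM(tuple(tree.taxa), chars, cells))


# ---------------------------------------------------------------------------
# random addition + hill climbing
# ---------------------------------------------------------------------------

def _edge_root_sets(tree: Tree, enc: Encoding) -> tuple[int, dict[tuple[int, int], int]]:
    """One down-pass + one up-pass giving (tree length, directional Fitch
    root set for the tree rooted on each edge)."""
    adj = tree.adj
    n = len(tree.taxa)
    combine = enc.combine
    leaf_sets = enc.leaf_sets
    root = next(x for x in adj if len(adj[x]) > 1)
    parent: dict[int, int | None] = {root: None}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                order.append(v)
                stack.append(v)
    D: dict[int, int] = {}
    total = 0
    for u in reversed(order):
        if u < n:
            D[u] = leaf_sets[u]
            continue
        it = iter(v for v in adj[u] if v != parent[u])
        s = D[next(it)]
        for v in it:
            s, st = combine(s, D[v])
            total += st
        D[u] = s
    U: dict[int, int] = {}
    for u in order:
        kids = [v for v in adj[u] if v != parent[u]]
        for v in kids:
            s = U[u] if parent[u] is not None else None
            for w in kids:
                if w is not v:
                    s = D[w] if s is None else combine(s, D[w])[0]
            U[v] = s
    roots: dict[tuple[int, int], int] = {}
    for v, p in parent.items():
        if p is None:
            continue
        roots[(min(v, p), max(v, p))] = combine(D[v], U[v])[0]
    return total, roots


def _random_addition(matrix_taxa: Sequence[str], enc: Encoding,
                     rng: random.Random) -> tuple[Tree, int]:
    """Greedy stepwise addition in a seeded random order; insertion ties are
    broken by the first edge in a deterministic traversal."""
    n = len(matrix_taxa)
    order = list(range(n))
    rng.shuffle(order)
    a, b, c = order[:3]
    adj = {a: {n}, b: {n}, c: {n}, n: {a, b, c}}
    tree = Tree(matrix_taxa, adj)
    nxt = n + 1
    join = enc.join_steps
    for t in order[3:]:
        base, roots = _edge_root_sets(tree, enc)
        leaf = enc.leaf_sets[t]
        best = None
        best_edge = None
        for e in sorted(roots):
            L = base + join(roots[e], leaf)
            if best is None or L < best:
                best, best_edge = L, e
        x, y = best_edge
        adj = tree.adj
        adj[x].discard(y)
        adj[y].discard(x)
        adj[nxt] = {x, y, t}
        adj[x].add(nxt)
        adj[y].add(nxt)
        adj[t] = {nxt}
        nxt += 1
    return tree, _tree_length_enc(tree, enc)


def _tree_length_enc(tree: Tree, enc: Encoding) -> int:
    from .fitch import tree_length
    return tree_length(tree, enc)


def _hill_climb(tree: Tree, length: int, enc: Encoding, swap: Swap
                ) -> tuple[Tree, int]:
    if swap == "nni":
        while True:
            from .fitch import tree_length
            best, best_tree = length, None
            for t2 in _enumerate_nni(tree):
                L = tree_length(t2, enc)
                if L < best:
                    best, best_tree = L, t2
            if best_tree is None:
                return tree, length
            tree, length = best_tree, best
    while True:
        best = length
        best_move = None
        for L, move, *_ in _sweep(tree, enc, swap):
            if L < best:
                best, best_move = L, move
        if best_move is None:
            return tree, length
        tree = _apply_tbr(tree, best_move)
        length = best


def heuristic_search(matrix: CharacterMatrix,
                     config: SearchConfig | None = None) -> TreeSet:
    """Random-addition + hill-climbing search with closure at the optimum.

    Every start builds a seeded greedy addition tree, hill-climbs over the
    configured neighbourhood accepting strict improvements, and the best
    trees found are then closed under the neighbourhood at the optimal
    length (swapping from every optimal tree until no new optimal topology
    appears).  With ``keep_margin > 0``, suboptimal trees encountered during
    closure are retained up to ``max_saved_trees``.
    """
    if matrix.n_taxa < 4:
        raise TreeError("search needs at least 4 taxa")
    config = config or SearchConfig()
    enc = Encoding(matrix)
    rng = random.Random(config.seed)
    result = TreeSet(config.keep_margin, config.max_saved_trees)
    starts: list[tuple[Tree, int]] = []
    for _ in range(config.n_starts):
        tree, L = _random_addition(matrix.taxa, enc, rng)
        tree, L = _hill_climb(tree, L, enc, config.swap)
        starts.append((tree, L))
    best = min(L for _, L in starts)
    for tree, L in starts:
        if L <= best + config.keep_margin:
            result.add(tree, L)
    close_under_swap(result, enc, config.swap)
    return result


def close_under_swap(treeset: TreeSet, enc: Encoding, swap: Swap,
                     max_expansions: int | None = None) -> None:
    """Expand optimal trees until no rearrangement yields a new optimal
    topology; suboptimal neighbours within ``treeset.keep_margin`` are also
    saved (subject to the tree-set cap)."""
    if swap == "nni":
        _close_nni(treeset, enc)
        return
    best = treeset.best_length
    margin = treeset.keep_margin
    frontier = [(k, t) for k, (t, L) in treeset._trees.items() if L == best]
    expanded: set[frozenset[int]] = set()
    n_exp = 0
    while frontier:
        key, tree = frontier.pop()
        if key in expanded:
            continue
        expanded.add(key)
        n_exp += 1
        if max_expansions is not None and n_exp > max_expansions:
            return
        n = len(tree.taxa)
        adj = tree.adj
        hi, lo = enc.hi, enc.lo
        restart = False
        for e in tree.edges():
            u, v = e
            cx = _component(adj, u, e, enc, n)
            cy = _component(adj, v, e, enc, n)
            base = cx.length + cy.length
            slack = best + margin - base
            if slack < 0:
                continue
            if swap == "tbr":
                pairs = ((x, y) for x in cx.cands for y in cy.cands)
            else:  # spr: one side keeps its original junction
                jx = cx.junction or cx.cands[0][0]
                jy = cy.junction or cy.cands[0][0]
                fx = [c for c in cx.cands if c[0] == jx]
                fy = [c for c in cy.cands if c[0] == jy]
                pairs = itertools.chain(
                    ((x, y) for x in fx for y in cy.cands),
                    ((x, y) for x in cx.cands for y in fy))
            for (ex, rx, bx), (ey, ry, by) in pairs:
                x = rx & ry
                zh = (((x | hi) - lo) & hi) ^ hi
                if zh:
                    st = zh.bit_count()
                    if st > slack:
                        continue
                else:
                    st = 0
                L = base + st
                k = _neighbor_splits(cx, bx, cy, by, n)
                if k in treeset:
                    continue
                t2 = _apply_tbr(tree, (e, ex, ey))
                if L < best:  # a better optimum found during closure
                    treeset.add(t2, L, key=k)
                    best = treeset.best_length
                    margin = treeset.keep_margin
                    frontier = [(kk, tt) for kk, (tt, LL)
                                in treeset._trees.items() if LL == best]
                    expanded = set()
                    restart = True
                    break
                if treeset.add(t2, L, key=k) and L == best:
                    frontier.append((k, t2))
            if restart:
                break


def _close_nni(treeset: TreeSet, enc: Encoding) -> None:
    from .fitch import tree_length
    best = treeset.best_length
    frontier = [(k, t) for k, (t, L) in treeset._trees.items() if L == best]
    while frontier:
        key, tree = frontier.pop()
        for t2 in _enumerate_nni(tree):
            L = tree_length(t2, enc)
            k = t2.canonical_key()
            if L <= best + treeset.keep_margin and k not in treeset:
                if treeset.add(t2, L, key=k) and L == best:
                    frontier.append((k, t2))


# ---------------------------------------------------------------------------
# exact search
# ---------------------------------------------------------------------------

class GuardError(RuntimeError):
    """Raised when branch-and-bound is asked for more taxa than its guard:
    the search is exponential and not intended for full-size matrices."""


def branch_and_bound(matrix: CharacterMatrix, guard_n: int = 12,
                     override: bool = False) -> TreeSet:
    """Exact search ("implicit enumeration"): returns ALL minimum-length
    binary topologies by stepwise taxon addition with an admissible bound
    (partial length plus outstanding per-character state diversity).  The
    result is independent of the addition order."""
    n = matrix.n_taxa
    if n < 4:
        raise TreeError("search needs at least 4 taxa")
    if n > guard_n and not override:
        raise GuardError(
            f"branch-and-bound on {n} taxa would enumerate an astronomically "
            f"large tree space; pass override=True (or raise guard_n) to force")
    enc = Encoding(matrix)
    taxa = matrix.taxa
    # State-diversity bound: a future taxon whose state is new to a column
    # must cost at least one extra step.  This is only sound for columns with
    # no ambiguous cells — a `?`/`-`/polymorphic cell among the placed taxa
    # can absorb a "new" state for free — so such columns are excluded.
    nchar = matrix.n_characters
    clean = [all(matrix.cells[i][c].kind == "observed" for i in range(n))
             for c in range(nchar)]
    seen_by_taxon: list[list[tuple[int, int]]] = []
    for i in range(n):
        lst = []
        for c in range(nchar):
            cell = matrix.cells[i][c]
            if clean[c] and cell.kind == "observed":
                s = next(iter(cell.states))
                lst.append((c, s))
        seen_by_taxon.append(lst)
    # quick upper bound from one greedy start + climb
    rng = random.Random(0)
    t0, L0 = _random_addition(taxa, enc, rng)
    t0, L0 = _hill_climb(t0, L0, enc, "spr")
    best = L0
    result = TreeSet(0)

    need = [set() for _ in range(nchar)]  # states still to appear
    for i in range(3, n):
        for c, s in seen_by_taxon[i]:
            need[c].add((i, s))

    def future_bound(placed_states: list[set[int]], next_i: int) -> int:
        extra = 0
        for c in range(nchar):
            coming = {s for i, s in need[c] if i >= next_i}
            extra += len(coming - placed_states[c])
        return extra

    a, b, c0 = 0, 1, 2
    adj = {a: {n}, b: {n}, c0: {n}, n: {a, b, c0}}
    base_tree = Tree(taxa, adj)
    placed: list[set[int]] = [set() for _ in range(nchar)]
    for i in (0, 1, 2):
        for c, s in seen_by_taxon[i]:
            placed[c].add(s)

    def recurse(tree: Tree, length: int, next_i: int,
                placed_states: list[set[int]]):
        nonlocal best
        if next_i == n:
            if length < best:
                best = length
                result.best_length = None
                result._trees.clear()
            if length == best:
                result.add(tree, length)
            return
        # the bound must see the states of the taxon being inserted, whose
        # cost is already inside L; otherwise a state introduced here and
        # recurring later is double-counted and the bound over-prunes
        ps = [set(s) for s in placed_states]
        for c, s in seen_by_taxon[next_i]:
            ps[c].add(s)
        fb = future_bound(ps, next_i + 1)
        base, roots = _edge_root_sets(tree, enc)
        leaf = enc.leaf_sets[next_i]
        for e in sorted(roots):
            L = base + enc.join_steps(roots[e], leaf)
            if L + fb > best:
                continue
            x, y = e
            node = n + next_i - 2
            t2 = tree.copy()
            t2.adj[x].discard(y)
            t2.adj[y].discard(x)
            t2.adj[node] = {x, y, next_i}
            t2.adj[x].add(node)
            t2.adj[y].add(node)
            t2.adj[next_i] = {node}
            recurse(t2, L, next_i + 1, ps)

    recurse(base_tree, _tree_length_enc(base_tree, enc), 3, placed)
    return result
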