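"""Unrooted leaf-labelled trees.

The tree type used throughout the package.  Leaves are indices ``0..n-1``
into a fixed, ordered taxon tuple; internal vertices are integers ``>= n``.
Topology is stored as an adjacency map.  Binary trees have internal degree 3;
consensus trees may contain polytomies.  Identity of an unrooted tree is its
set of non-trivial bipartitions (splits), each represented canonically as the
leaf bitmask not containing leaf 0.
"""
from __future__ import annotations

import itertools
import random
from typing import Iterable, Iterator, Sequence


class TreeError(ValueError):
    pass


class Tree:
    """An unrooted tree over an ordered taxon tuple.

    Parameters
    ----------
    taxa:
        Ordered taxon names; leaf ``i`` is ``taxa[i]``.
    adj:
        Adjacency map ``node -> set of neighbours``.  Leaves must have
        degree 1, internal vertices degree >= 3 (a two-leaf tree, leaf-leaf
        edge only, is also accepted).
    """

    __slots__ = ("taxa", "adj")

    def __init__(self, taxa: Sequence[str], adj: dict[int, set[int]]):
        self.taxa = tuple(taxa)
        self.adj = adj

    # -- construction -------------------------------------------------
    @classmethod
    def star(cls, taxa: Sequence[str]) -> "Tree":
        n = len(taxa)
        hub = n
        adj: dict[int, set[int]] = {hub: set(range(n))}
        for i in range(n):
            adj[i] = {hub}
        return cls(taxa, adj)

    @classmethod
    def from_newick(cls, text: str, taxa: Sequence[str] | None = None) -> "Tree":
        """Parse a Newick string (branch lengths allowed and discarded).

        A rooted (bifurcating-root) Newick is unrooted by suppressing the
        degree-2 root.  If *taxa* is given, leaf labels must match it and the
        leaf indexing follows it; otherwise taxa are ordered alphabetically.
        """
        text = text.strip()
        if not text.endswith(";"):
            raise TreeError("newick must end with ';'")
        tokens = _tokenize_newick(text[:-1])
        labels: list[str] = []
        edges: list[tuple[int, int]] = []
        next_id = itertools.count(start=10**9)  # provisional internal ids

        def parse(pos: int) -> tuple[int, int]:
            if tokens[pos] == "(":
                node = next(next_id)
                pos += 1
                while True:
                    child, pos = parse(pos)
                    edges.append((node, child))
                    if tokens[pos] == ",":
                        pos += 1
                        continue
                    if tokens[pos] == ")":
                        pos += 1
                        break
                # optional internal label / branch length
                while pos < len(tokens) and tokens[pos] not in ",()":
                    pos += 1
                return node, pos
            label = tokens[pos]
            if label in ",()":
                raise TreeError(f"unexpected token {label!r}")
            name = label.split(":")[0]
            labels.append(name)
            return -len(labels), pos + 1  # provisional leaf id

        root, pos = parse(0)
        if pos != len(tokens):
            raise TreeError("trailing newick content")
        if taxa is None:
            taxa = sorted(labels)
        index = {t: i for i, t in enumerate(taxa)}
        if set(labels) != set(taxa) or len(labels) != len(taxa):
            raise TreeError("newick leaf labels do not match taxa")
        n = len(taxa)
        remap: dict[int, int] = {}
        counter = itertools.count(n)
        for a, b in edges:
            for x in (a, b):
                if x not in remap:
                    remap[x] = index[labels[-x - 1]] if x < 0 else next(counter)
        if root not in remap:  # single-leaf newick
            remap[root] = index[labels[-root - 1]]
        adj: dict[int, set[int]] = {}
        for a, b in edges:
            adj.setdefault(remap[a], set()).add(remap[b])
            adj.setdefault(remap[b], set()).add(remap[a])
        if not adj:
            adj = {remap[root]: set()}
        tree = cls(taxa, adj)
        tree._suppress_degree_two()
        return tree

    def _suppress_degree_two(self) -> None:
        n = len(self.taxa)
        for node in [x for x in self.adj if x >= n and len(self.adj[x]) == 2]:
            a, b = self.adj[node]
            self.adj[a].discard(node)
            self.adj[b].discard(node)
            self.adj[a].add(b)
            self.adj[b].add(a)
            del self.adj[node]

    def copy(self) -> "Tree":
        return Tree(self.taxa, {k: set(v) for k, v in self.adj.items()})

    # -- basic queries ------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in self.adj for v in self.adj[u] if u < v]

    def is_binary(self) -> bool:
        n = len(self.taxa)
        return all(len(s) == 3 for x, s in self.adj.items() if x >= n)

    def validate(self) -> None:
        n = len(self.taxa)
        for x, s in self.adj.items():
            want = 1 if x < n else 3
            if x < n and len(s) != 1 and len(self.adj) > 2:
                raise TreeError(f"leaf {x} has degree {len(s)}")
            if x >= n and len(s) < want:
                raise TreeError(f"internal vertex {x} has degree {len(s)}")
            for y in s:
                if x not in self.adj.get(y, ()):
                    raise TreeError("asymmetric adjacency")

    # -- splits and identity -------------------------------------------
    def _below_masks(self) -> tuple[dict[int, int], dict[int, int | None]]:
        """Leaf bitmask below each node, rooted at an internal vertex."""
        n = len(self.taxa)
        root = next((x for x in self.adj if len(self.adj[x]) > 1), None)
        if root is None:  # two-leaf tree
            root = next(iter(self.adj))
        parent: dict[int, int | None] = {root: None}
        order = [root]
        stack = [root]
        while stack:
            u = stack.pop()
            for v in self.adj[u]:
                if v != parent[u]:
                    parent[v] = u
                    order.append(v)
                    stack.append(v)
        below: dict[int, int] = {}
        for u in reversed(order):
            m = (1 << u) if u < n else 0
            for v in self.adj[u]:
                if v != parent[u]:
                    m |= below[v]
            below[u] = m
        return below, parent

    def splits(self) -> frozenset[int]:
        """Non-trivial bipartitions as bitmasks of the side without leaf 0."""
        n = len(self.taxa)
        full = (1 << n) - 1
        below, parent = self._below_masks()
        out = set()
        for v, p in parent.items():
            if p is None:
                continue
            m = below[v]
            if m & 1:
                m = full ^ m
            if m.bit_count() >= 2 and (full ^ m).bit_count() >= 2:
                out.add(m)
        return frozenset(out)

    def canonical_key(self) -> frozenset[int]:
        """Equal for two trees iff they induce the same bipartition set."""
        return self.splits()

    def has_split(self, mask: int) -> bool:
        n = len(self.taxa)
        if mask & 1:
            mask ^= (1 << n) - 1
        return mask in self.splits()

    # -- rooted views --------------------------------------------------
    def rooted_orientation(self, outgroup: str | None = None):
        """Return (order, parent) for a traversal rooted next to *outgroup*
        (or an arbitrary internal vertex).  ``order`` is preorder."""
        n = len(self.taxa)
        if outgroup is not None:
            og = self.taxa.index(outgroup)
            root = next(iter(self.adj[og]))
        else:
            root = next((x for x in self.adj if len(self.adj[x]) > 1),
                        next(iter(self.adj)))
        parent: dict[int, int | None] = {root: None}
        order = [root]
        stack = [root]
        while stack:
            u = stack.pop()
            for v in self.adj[u]:
                if v != parent[u]:
                    parent[v] = u
                    order.append(v)
                    stack.append(v)
        return order, parent

    # -- newick -------------------------------------------------------
    def to_newick(self, outgroup: str | None = None,
                  edge_labels: dict[int, str] | None = None) -> str:
        """Write Newick.  With *outgroup*, the string is written rooted on the
        edge leading to that leaf (display rooting only).  *edge_labels* maps
        a split bitmask to an internal-node label (support annotation)."""
        n = len(self.taxa)
        full = (1 << n) - 1
        below, _ = self._below_masks()

        def label_for(node: int, parent: int) -> str:
            if edge_labels is None:
                return ""
            m = below[node] if node in below else 0
            if m & 1:
                m = full ^ m
            return edge_labels.get(m, "")

        def write(node: int, parent: int) -> str:
            if node < n:
                return _quote(self.taxa[node])
            kids = [v for v in self.adj[node] if v != parent]
            inner = ",".join(write(v, node) for v in kids)
            return f"({inner}){label_for(node, parent)}"

        if len(self.adj) == 1:
            return _quote(self.taxa[0]) + ";"
        if outgroup is None:
            root = next((x for x in self.adj if len(self.adj[x]) > 1),
                        next(iter(self.adj)))
            kids = list(self.adj[root])
            inner = ",".join(write(v, root) for v in kids)
            return f"({inner});"
        og = self.taxa.index(outgroup)
        other = next(iter(self.adj[og]))
        return f"({_quote(self.taxa[og])},{write(other, og)});"

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree(n={len(self.taxa)}, {self.to_newick()})"

    def __eq__(self, other) -> bool:
        return (isinstance(other, Tree) and self.taxa == other.taxa
                and self.splits() == other.splits())

    def __hash__(self) -> int:
        return hash((self.taxa, self.splits()))


def _quote(name: str) -> str:
    if any(c in name for c in " (),:;[]'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def _tokenize_newick(text: str) -> list[str]:
    tokens: list[str] = []
    buf = ""
    i = 0
    while i < len(text):
        c = text[i]
        if c == "'":
            j = i + 1
            while j < len(text):
                if text[j] == "'" and j + 1 < len(text) and text[j + 1] == "'":
                    j += 2
                    continue
                if text[j] == "'":
                    break
                j += 1
            buf += text[i + 1:j].replace("''", "'")
            i = j + 1
            continue
        if c in "(),":
            if buf.strip():
                tokens.append(buf.strip())
            buf = ""
            tokens.append(c)
        elif c.isspace():
            pass
        else:
            buf += c
        i += 1
    if buf.strip():
        tokens.append(buf.strip())
    return tokens


def tree_from_splits(taxa: Sequence[str], splits: Iterable[int]) -> Tree:
    """Build the (possibly polytomous) tree containing exactly *splits*.

    The splits must be pairwise compatible (as is guaranteed for the
    intersection of the split sets of trees on the same taxa).
    """
    n = len(taxa)
    full = (1 << n) - 1
    masks = sorted({m if not (m & 1) else full ^ m for m in splits},
                   key=lambda m: m.bit_count())
    # start from a star; repeatedly pull the leaves/subtree-roots of each
    # split under a fresh internal vertex, smallest splits first
    tree = Tree.star(taxa)
    adj = tree.adj
    counter = itertools.count(n + 1)
    group_root = {1 << i: i for i in range(n)}
    parent_hub = {i: n for i in range(n)}  # group root -> attachment vertex
    for m in masks:
        # members of this split are the roots of already-formed sub-groups
        members = []
        rest = m
        for gm in sorted(group_root, key=lambda g: -g.bit_count()):
            if gm & m == gm and gm & rest == gm:
                members.append(group_root[gm])
                rest ^= gm
        if rest:
            raise TreeError("incompatible splits")
        hubs = {parent_hub[v] for v in members}
        if len(hubs) != 1:
            raise TreeError("incompatible splits")
        hub = hubs.pop()
        new = next(counter)
        adj[new] = set(members) | {hub}
        for v in members:
            adj[v].discard(hub)
            adj[hub].discard(v)
            adj[v].add(new)
            parent_hub[v] = new
        adj[hub].add(new)
        for gm in [g for g in group_root if g & m]:
            del group_root[gm]
        group_root[m] = new
        parent_hub[new] = hub
    tree._suppress_degree_two()
    return tree


def random_binary_tree(taxa: Sequence[str], rng: random.Random) -> Tree:
    """Uniform random binary unrooted topology via sequential edge insertion."""
    n = len(taxa)
    if n < 3:
        if n == 2:
            return Tree(taxa, {0: {1}, 1: {0}})
        raise TreeError("need >= 2 taxa")
    adj: dict[int, set[int]] = {0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}
    nxt = n + 1
    for leaf in range(3, n):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        a, b = rng.choice(edges)
        adj[a].discard(b)
        adj[b].discard(a)
        adj[nxt] = {a, b, leaf}
        adj[a].add(nxt)
        adj[b].add(nxt)
        adj[leaf] = {nxt}
        nxt += 1
    return Tree(taxa, adj)


def all_topologies(taxa: Sequence[str]) -> Iterator[Tree]:
    """Exhaustively enumerate all unrooted binary topologies (small n only)."""
    n = len(taxa)
    if n > 9:
        raise TreeError("exhaustive enumeration is limited to 9 taxa")

    def expand(adj: dict[int, set[int]], leaf: int, nxt: int) -> Iterator[dict]:
        if leaf == n:
            yield adj
            return
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        for a, b in edges:
            new = {k: set(s) for k, s in adj.items()}
            new[a].discard(b)
            new[b].discard(a)
            new[nxt] = {a, b, leaf}
            new[a].add(nxt)
            new[b].add(nxt)
            new[leaf] = {nxt}
            yield from expand(new, leaf + 1, nxt + 1)

    base = {0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}
    for adj in expand(base, 3, n + 1):
        yield Tree(taxa, adj)
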