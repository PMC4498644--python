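"""Fitch optimization for unordered, equally weighted multistate characters.

The core is a bit-parallel kernel: each character occupies an 8-bit field of
one arbitrary-precision integer per node, with bit ``s`` of a field set when
state ``s`` is admissible.  Missing and inapplicable cells admit the full
state range of their character; polymorphic cells admit their coded set.  A
set intersection/union step over all characters is then a handful of integer
operations, and empty intersections (the events that cost one step each) are
detected per field with a carry trick, so scoring a tree costs O(n) big-int
operations regardless of the number of characters.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .matrix import CharacterMatrix
from .tree import Tree, TreeError

_FIELD = 8  # bits per character; states 0..7 supported


class Encoding:
    """Bit-packed admissible-state sets for one matrix (optionally with
    resampled/duplicated columns, as in bootstrap pseudoreplicates)."""

    __slots__ = ("taxa", "leaf_sets", "n_fields", "lo", "hi", "columns")

    def __init__(self, matrix: CharacterMatrix,
                 columns: Sequence[int] | None = None):
        if columns is None:
            columns = range(matrix.n_characters)
        self.columns = tuple(columns)
        self.taxa = matrix.taxa
        self.n_fields = len(self.columns)
        self.lo = sum(1 << (_FIELD * i) for i in range(self.n_fields))
        self.hi = self.lo << (_FIELD - 1)
        self.leaf_sets = []
        for row in matrix.cells:
            v = 0
            for f, c in enumerate(self.columns):
                mask = 0
                for s in row[c].states:
                    mask |= 1 << s
                v |= mask << (_FIELD * f)
            self.leaf_sets.append(v)

    def combine(self, a: int, b: int) -> tuple[int, int]:
        """Fitch set combination: per character, intersection where non-empty
        (no step), union where empty (one step).  Returns (sets, steps)."""
        hi, lo = self.hi, self.lo
        x = a & b
        zero_hi = (((x | hi) - lo) & hi) ^ hi
        if not zero_hi:
            return x, 0
        m = (zero_hi >> (_FIELD - 1)) * 0xFF
        return (x & ~m) | ((a | b) & m), zero_hi.bit_count()

    def join_steps(self, a: int, b: int) -> int:
        """Steps incurred by joining two directional state sets."""
        x = a & b
        return (((((x | self.hi) - self.lo) & self.hi) ^ self.hi)).bit_count()

    def event_fields(self, a: int, b: int) -> list[int]:
        """Field indices where a & b is empty (per-character step events)."""
        x = a & b
        zero_hi = (((x | self.hi) - self.lo) & self.hi) ^ self.hi
        out = []
        f = 0
        while zero_hi:
            if zero_hi & (1 << (_FIELD * f + _FIELD - 1)):
                out.append(f)
                zero_hi &= ~(1 << (_FIELD * f + _FIELD - 1))
            f += 1
        return out


@dataclass(frozen=True)
class LengthReport:
    """Total parsimony length and its per-character decomposition."""

    total: int
    per_character: tuple[int, ...]

    def __post_init__(self):
        if self.total != sum(self.per_character):
            raise ValueError("inconsistent length report")


def _check_leaves(tree: Tree, matrix: CharacterMatrix) -> None:
    if set(tree.taxa) != set(matrix.taxa):
        raise TreeError("tree leaves do not match matrix taxa")


def tree_length(tree: Tree, enc: Encoding) -> int:
    """Total Fitch length (fast path; leaf order must match the encoding)."""
    adj = tree.adj
    root = next(x for x in adj if len(adj[x]) > 1)
    n = len(tree.taxa)
    order, parent = tree.rooted_orientation()
    sets: dict[int, int] = {}
    steps = 0
    combine = enc.combine
    leaf_sets = enc.leaf_sets
    for node in reversed(order):
        if node < n:
            sets[node] = leaf_sets[node]
            continue
        it = iter(v for v in adj[node] if v != parent[node])
        s = sets[next(it)]
        for v in it:
            s, st = combine(s, sets[v])
            steps += st
        sets[node] = s
    return steps


def fitch_length(tree: Tree, matrix: CharacterMatrix) -> LengthReport:
    """Parsimony length of *tree* under Fitch optimization.

    The tree may be scored at any rooting; the count is root-invariant.
    Missing and inapplicable terminals enter as the full admissible range,
    polymorphic terminals as their coded set, so a polymorphic cell is not
    charged a step when compatible with its neighbourhood.
    """
    _check_leaves(tree, matrix)
    if tuple(tree.taxa) != matrix.taxa:
        from .matrix import subset_taxa
        matrix = subset_taxa(matrix, tree.taxa)
    enc = Encoding(matrix)
    adj = tree.adj
    n = len(tree.taxa)
    order, parent = tree.rooted_orientation()
    per = [0] * matrix.n_characters
    sets: dict[int, int] = {}
    for node in reversed(order):
        if node < n:
            sets[node] = enc.leaf_sets[node]
            continue
        it = iter(v for v in adj[node] if v != parent[node])
        s = sets[next(it)]
        for v in it:
            for f in enc.event_fields(s, sets[v]):
                per[f] += 1
            s, _ = enc.combine(s, sets[v])
        sets[node] = s
    return LengthReport(sum(per), tuple(per))


def column_lower_bound(matrix: CharacterMatrix) -> int:
    """An admissible lower bound on the minimum tree length: each character
    needs at least (number of distinct singleton observed states - 1) steps
    on any tree."""
    total = 0
    for c in range(matrix.n_characters):
        observed = {next(iter(row[c].states))
                    for row in matrix.cells if row[c].kind == "observed"}
        total += max(0, len(observed) - 1)
    return total


def brute_force_length(tree: Tree, matrix: CharacterMatrix) -> int:
    """Exhaustive minimum over all internal-node state assignments.

    Exponential; intended as an independent check at small n.
    """
    _check_leaves(tree, matrix)
    if tuple(tree.taxa) != matrix.taxa:
        from .matrix import subset_taxa
        matrix = subset_taxa(matrix, tree.taxa)
    import itertools
    n = len(tree.taxa)
    internal = [x for x in tree.adj if x >= n]
    edges = tree.edges()
    total = 0
    for c, char in enumerate(matrix.characters):
        states = range(char.max_state + 1)
        best = None
        leaf_opts = {i: sorted(matrix.cells[i][c].states) for i in range(n)}
        nodes = list(range(n)) + internal
        opts = [leaf_opts[x] if x < n else list(states) for x in nodes]
        for assign in itertools.product(*opts):
            a = dict(zip(nodes, assign))
            steps = sum(1 for u, v in edges if a[u] != a[v])
            if best is None or steps < best:
                best = steps
        total += best
    return total
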