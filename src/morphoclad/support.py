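"""Clade support: strict consensus, bootstrap frequencies, decay (Bremer)
indices, and the dual-analysis robustness filter.

Decay indices are computed TNT-style from a saved-tree pool: starting from
the minimum-length trees, TBR rearrangements are explored saving every
distinct tree up to ``margin`` steps longer (bounded by a tree cap), and a
clade's decay index is the smallest length excess among saved trees that
lack it.  A clade contradicted by no saved tree is reported censored
(">margin") rather than given a fabricated value.
"""
from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

from .fitch import Encoding, tree_length
from .matrix import CharacterMatrix
from .search import SearchConfig, TreeSet, close_under_swap, heuristic_search
from .tree import Tree, TreeError, tree_from_splits


@dataclass(frozen=True)
class Bipartition:
    """An unrooted split of a fixed taxon universe, stored by its canonical
    side: the smaller subset, ties broken by the lexicographically smallest
    sorted member tuple."""

    universe: frozenset[str]
    side: frozenset[str]

    def __post_init__(self):
        if not self.side < self.universe:
            raise TreeError("split side must be a proper subset of the universe")
        other = self.universe - self.side
        if len(other) < len(self.side) or (
                len(other) == len(self.side)
                and sorted(other) < sorted(self.side)):
            object.__setattr__(self, "side", frozenset(other))

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(sorted(self.side))

    @property
    def informative(self) -> bool:
        return 2 <= len(self.side) <= len(self.universe) - 2

    def restrict(self, taxa: Sequence[str]) -> "Bipartition | None":
        """The split induced on a taxon subset; None if uninformative there."""
        sub = frozenset(taxa)
        if not sub <= self.universe:
            raise TreeError("restriction taxa outside the universe")
        a = self.side & sub
        if 2 <= len(a) <= len(sub) - 2:
            return Bipartition(sub, a)
        return None

    @classmethod
    def from_mask(cls, mask: int, taxa: Sequence[str]) -> "Bipartition":
        side = frozenset(taxa[i] for i in range(len(taxa)) if mask >> i & 1)
        return cls(frozenset(taxa), side)

    def mask(self, taxa: Sequence[str]) -> int:
        index = {t: i for i, t in enumerate(taxa)}
        m = 0
        for t in self.side:
            m |= 1 << index[t]
        if m & 1:
            m ^= (1 << len(taxa)) - 1
        return m


def tree_bipartitions(tree: Tree) -> set[Bipartition]:
    """The informative splits of a tree as Bipartition objects."""
    return {Bipartition.from_mask(m, tree.taxa) for m in tree.splits()}


@dataclass(frozen=True)
class SupportRecord:
    """Support values attached to one split.  ``bremer_censored_at=k`` means
    no tree within ``k`` extra steps contradicted the split (reported ">k");
    ``bremer`` is then None."""

    bipartition: Bipartition
    bootstrap_pct: float | None = None
    bremer: int | None = None
    bremer_censored_at: int | None = None

    def __post_init__(self):
        if self.bootstrap_pct is not None and not 0 <= self.bootstrap_pct <= 100:
            raise ValueError("bootstrap percentage out of range")
        if self.bremer is not None and self.bremer < 0:
            raise ValueError("negative decay index")
        if (self.bremer is None) == (self.bremer_censored_at is None):
            if self.bremer is not None:
                raise ValueError("decay index cannot be both valued and censored")

    @property
    def bremer_display(self) -> str:
        if self.bremer_censored_at is not None:
            return f">{self.bremer_censored_at}"
        return "" if self.bremer is None else str(self.bremer)

    def bremer_at_least(self, threshold: int) -> bool:
        if self.bremer_censored_at is not None:
            return self.bremer_censored_at >= threshold
        return self.bremer is not None and self.bremer >= threshold


def strict_consensus(trees: TreeSet | Sequence[Tree]) -> Tree:
    """The (possibly polytomous) tree whose splits are exactly those present
    in every input tree."""
    tl = trees.trees if isinstance(trees, TreeSet) else list(trees)
    if not tl:
        raise TreeError("strict consensus of an empty tree set")
    taxa = tl[0].taxa
    for t in tl[1:]:
        if t.taxa != taxa:
            raise TreeError("strict consensus requires identical leaf sets")
    common = set(tl[0].splits())
    for t in tl[1:]:
        common &= t.splits()
        if not common:
            break
    return tree_from_splits(taxa, common)


DEFAULT_BOOTSTRAP_CONFIG = SearchConfig(n_starts=5, swap="spr",
                                        max_saved_trees=200)


def resample_columns(matrix: CharacterMatrix, rng: random.Random) -> CharacterMatrix:
    """One bootstrap pseudoreplicate: characters drawn with replacement
    (whole columns, cells intact); dimensions preserved."""
    k = matrix.n_characters
    cols = [rng.randrange(k) for _ in range(k)]
    chars = tuple(
        type(matrix.characters[c])(
            index=i, label=matrix.characters[c].label,
            state_labels=matrix.characters[c].state_labels)
        for i, c in enumerate(cols))
    cells = tuple(tuple(row[c] for c in cols) for row in matrix.cells)
    return CharacterMatrix(matrix.taxa, chars, cells, aliases=matrix.aliases)


def bootstrap_support(matrix: CharacterMatrix,
                      reference_splits: Sequence[Bipartition],
                      replicates: int = 1000,
                      config: SearchConfig | None = None,
                      seed: int = 0) -> list[SupportRecord]:
    """Frequency (percent) of each reference split in the strict consensus
    of a heuristic search on each character-resampled pseudoreplicate."""
    if replicates < 1:
        raise ValueError("need at least one replicate")
    config = config or DEFAULT_BOOTSTRAP_CONFIG
    rng = random.Random(seed)
    hits = [0] * len(reference_splits)
    masks = [b.mask(matrix.taxa) for b in reference_splits]
    for r in range(replicates):
        rep = resample_columns(matrix, rng)
        rep_config = SearchConfig(
            mode=config.mode, n_starts=config.n_starts, swap=config.swap,
            seed=rng.randrange(2**32), keep_margin=0,
            max_saved_trees=config.max_saved_trees)
        found = heuristic_search(rep, rep_config)
        cons = strict_consensus(found.optimal_trees())
        present = cons.splits()
        for i, m in enumerate(masks):
            if m in present:
                hits[i] += 1
    return [SupportRecord(b, bootstrap_pct=100.0 * h / replicates)
            for b, h in zip(reference_splits, hits)]


def bremer_pool(matrix: CharacterMatrix, mpts: TreeSet, margin: int = 3,
                max_saved_trees: int = 10000) -> TreeSet:
    """All distinct trees within ``margin`` steps of the optimum reachable by
    TBR from the minimum-length trees, expanding every saved tree once
    (bounded by the tree cap)."""
    if margin < 1:
        raise ValueError("margin must be at least 1")
    enc = Encoding(matrix)
    pool = TreeSet(keep_margin=margin, max_saved_trees=max_saved_trees)
    for t, L in mpts.items():
        pool.add(t, L)
    if pool.best_length != mpts.best_length:
        raise TreeError("tree set inconsistent with its recorded optimum")
    # frontier over ALL saved trees, each expanded once
    from .search import _component, _apply_tbr, _neighbor_splits
    expanded: set[frozenset[int]] = set()
    best = pool.best_length
    n = len(matrix.taxa)
    hi, lo = enc.hi, enc.lo
    while True:
        todo = [(k, t) for k, (t, _L) in pool._trees.items()
                if k not in expanded]
        if not todo or len(pool) >= max_saved_trees:
            break
        for key, tree in todo:
            expanded.add(key)
            adj = tree.adj
            for e in tree.edges():
                u, v = e
                cx = _component(adj, u, e, enc, n)
                cy = _component(adj, v, e, enc, n)
                base = cx.length + cy.length
                slack = best + margin - base
                if slack < 0:
                    continue
                for ex, rx, bx in cx.cands:
                    for ey, ry, by in cy.cands:
                        x = rx & ry
                        zh = (((x | hi) - lo) & hi) ^ hi
                        st = zh.bit_count() if zh else 0
                        if st > slack:
                            continue
                        k = _neighbor_splits(cx, bx, cy, by, n)
                        if k in pool._trees:
                            continue
                        pool.add(_apply_tbr(tree, (e, ex, ey)), base + st,
                                 key=k)
                        if len(pool) >= max_saved_trees:
                            break
    return pool


def bremer_support(matrix: CharacterMatrix, mpts: TreeSet, margin: int = 3,
                   config: SearchConfig | None = None,
                   splits: Sequence[Bipartition] | None = None
                   ) -> list[SupportRecord]:
    """Decay index of each strict-consensus split of the minimum-length
    trees (or of ``splits`` if given), from a TBR-explored tree pool."""
    cap = config.max_saved_trees if config else 10000
    pool = bremer_pool(matrix, mpts, margin, cap)
    best = pool.best_length
    if splits is None:
        cons = strict_consensus(mpts.optimal_trees())
        splits = sorted(tree_bipartitions(cons), key=lambda b: b.members)
    records = []
    for b in splits:
        m = b.mask(matrix.taxa)
        worst = None
        for t, L in pool.items():
            if m not in t.splits():
                excess = L - best
                if worst is None or excess < worst:
                    worst = excess
                    if worst == 0:
                        break
        if worst is None:
            records.append(SupportRecord(b, bremer_censored_at=margin))
        else:
            records.append(SupportRecord(b, bremer=worst))
    return records


def exhaustive_bremer(matrix: CharacterMatrix,
                      splits: Sequence[Bipartition]) -> list[SupportRecord]:
    """Exact decay indices by scoring every topology (small taxon sets only):
    decay = (shortest tree lacking the split) - (shortest tree)."""
    from .tree import all_topologies
    n = matrix.n_taxa
    if n > 9:
        raise TreeError("exhaustive decay computation is limited to 9 taxa")
    enc = Encoding(matrix)
    masks = [b.mask(matrix.taxa) for b in splits]
    best = None
    best_without: list[int | None] = [None] * len(splits)
    for t in all_topologies(matrix.taxa):
        L = tree_length(t, enc)
        if best is None or L < best:
            best = L
        present = t.splits()
        for i, m in enumerate(masks):
            if m not in present:
                if best_without[i] is None or L < best_without[i]:
                    best_without[i] = L
    return [SupportRecord(b, bremer=(bw - best))
            for b, bw in zip(splits, best_without)]


def robust_clades(consensus_splits_1: Sequence[Bipartition],
                  bremer_1: Sequence[SupportRecord],
                  consensus_splits_2: Sequence[Bipartition],
                  bremer_2: Sequence[SupportRecord],
                  threshold: int = 3) -> list[Bipartition]:
    """Splits (compared on the taxa shared by both analyses) present in both
    consensus trees with decay index >= threshold in both analyses."""
    shared = tuple(sorted(
        (frozenset.union(*[b.universe for b in consensus_splits_1])
         if consensus_splits_1 else frozenset())
        & (frozenset.union(*[b.universe for b in consensus_splits_2])
           if consensus_splits_2 else frozenset())))
    if not shared:
        return []

    def project(splits, records):
        out = {}
        sup = {r.bipartition: r for r in records}
        for b in splits:
            rb = b.restrict(shared)
            if rb is None:
                continue
            r = sup.get(b)
            ok = (threshold <= 0) or (r is not None and r.bremer_at_least(threshold))
            # keep the strongest statement if two splits project to the same one
            out[rb] = out.get(rb, False) or ok
        return out

    p1 = project(consensus_splits_1, bremer_1)
    p2 = project(consensus_splits_2, bremer_2)
    kept = [b for b in p1 if p1[b] and p2.get(b, False)]
    return sorted(kept, key=lambda b: b.members)


def support_table(records: Sequence[SupportRecord]) -> str:
    """Support records as TSV: split_id, member_taxa, bootstrap_pct, bremer."""
    lines = ["split_id\tmember_taxa\tbootstrap_pct\tbremer"]
    for i, r in enumerate(records, 1):
        boot = "" if r.bootstrap_pct is None else f"{r.bootstrap_pct:.1f}"
        lines.append(f"s{i}\t{','.join(r.bipartition.members)}\t{boot}\t"
                     f"{r.bremer_display}")
    return "\n".join(lines) + "\n"
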