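import random

import pytest
from hypothesis import given, settings, strategies as st

from morphoclad.matrix import parse_matrix
from morphoclad.search import SearchConfig, TreeSet, branch_and_bound
from morphoclad.support import (Bipartition, SupportRecord, bootstrap_support,
                                bremer_support, exhaustive_bremer,
                                resample_columns, robust_clades,
                                strict_consensus, support_table,
                                tree_bipartitions)
from morphoclad.tree import Tree, TreeError, all_topologies, random_binary_tree

from helpers import congruent_matrix, random_matrix


class TestBipartition:
    def test_canonical_side_is_smaller(self):
        uni = frozenset("ABCDE")
        b = Bipartition(uni, frozenset("ABC"))
        assert b.side == frozenset("DE")
        assert Bipartition(uni, frozenset("DE")) == b

    def test_mask_round_trip(self):
        taxa = ("A", "B", "C", "D", "E")
        b = Bipartition(frozenset(taxa), frozenset("DE"))
        assert Bipartition.from_mask(b.mask(taxa), taxa) == b

    def test_restrict_drops_uninformative(self):
        b = Bipartition(frozenset("ABCDE"), frozenset("DE"))
        assert b.restrict(("A", "B", "D", "E")) == Bipartition(
            frozenset("ABDE"), frozenset("DE"))
        assert b.restrict(("A", "B", "C", "D")) is None

    def test_side_must_be_proper_subset(self):
        with pytest.raises(TreeError):
            Bipartition(frozenset("AB"), frozenset("AB"))


class TestStrictConsensus:
    def test_single_tree_identity(self):
        t = Tree.from_newick("((A,B),(C,(D,E)));")
        assert strict_consensus([t]).splits() == t.splits()

    def test_all_three_quartets_give_star(self):
        cons = strict_consensus(list(all_topologies(list("ABCD"))))
        assert cons.splits() == frozenset()

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=15)
    def test_splits_are_exact_intersection(self, seed):
        rng = random.Random(seed)
        taxa = [f"t{i}" for i in range(7)]
        trees = [random_binary_tree(taxa, rng) for _ in range(4)]
        cons = strict_consensus(trees)
        want = trees[0].splits()
        for t in trees[1:]:
            want &= t.splits()
        assert cons.splits() == want

    def test_leaf_set_mismatch_errors(self):
        with pytest.raises(TreeError):
            strict_consensus([Tree.from_newick("((A,B),(C,D));"),
                              Tree.from_newick("((A,B),(C,E));")])

    def test_empty_input_errors(self):
        with pytest.raises(TreeError):
            strict_consensus([])


class TestBootstrap:
    def test_resample_preserves_dimensions(self, bundled):
        rep = resample_columns(bundled, random.Random(0))
        assert rep.n_taxa == bundled.n_taxa
        assert rep.n_characters == bundled.n_characters

    def test_homoplasy_free_matrix_gives_100_percent(self):
        tree = random_binary_tree([f"t{i}" for i in range(8)],
                                  random.Random(3))
        m = congruent_matrix(tree, copies=20)
        splits = sorted(tree_bipartitions(tree), key=lambda b: b.members)
        recs = bootstrap_support(
            m, splits, replicates=10,
            config=SearchConfig(n_starts=2, swap="spr", max_saved_trees=50),
            seed=0)
        assert all(r.bootstrap_pct == 100.0 for r in recs)

    def test_deterministic_under_seed(self):
        rng = random.Random(5)
        m = random_matrix(rng, 7, 15, max_state=1, p_missing=0.1)
        t = branch_and_bound(m).optimal_trees()[0]
        splits = sorted(tree_bipartitions(t), key=lambda b: b.members)
        cfg = SearchConfig(n_starts=2, swap="spr", max_saved_trees=50)
        a = bootstrap_support(m, splits, replicates=20, config=cfg, seed=7)
        b = bootstrap_support(m, splits, replicates=20, config=cfg, seed=7)
        assert [r.bootstrap_pct for r in a] == [r.bootstrap_pct for r in b]
        assert all(0 <= r.bootstrap_pct <= 100 for r in a)


class TestBremer:
    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=8)
    def test_equals_exhaustive_decay_on_six_taxa(self, seed):
        rng = random.Random(seed)
        m = random_matrix(rng, 6, 12, max_state=rng.randrange(1, 3),
                          p_missing=0.1)
        mpts = branch_and_bound(m)
        cons = strict_consensus(mpts.optimal_trees())
        splits = sorted(tree_bipartitions(cons), key=lambda b: b.members)
        if not splits:
            return
        margin = 12
        got = bremer_support(m, mpts, margin=margin,
                             config=SearchConfig(max_saved_trees=200000))
        exact = exhaustive_bremer(m, splits)
        for g, e in zip(got, exact):
            assert g.bipartition == e.bipartition
            if g.bremer_censored_at is not None:
                assert e.bremer > margin
            else:
                assert g.bremer == e.bremer

    def test_split_absent_from_an_mpt_has_decay_zero(self):
        # characters support only {A,B} and {C,D}: the three resolutions of
        # the remaining star are equally parsimonious, so every split beyond
        # the consensus is contradicted at +0
        m = parse_matrix("A 10\nB 10\nC 01\nD 01\nE 00\nF 00",
                         dialect="simple")
        mpts = branch_and_bound(m)
        assert len(mpts.optimal_trees()) > 1
        cons_splits = strict_consensus(mpts.optimal_trees()).splits()
        one = mpts.optimal_trees()[0]
        extra = [Bipartition.from_mask(s, m.taxa)
                 for s in one.splits() - cons_splits]
        if extra:
            recs = bremer_support(m, mpts, margin=3, splits=extra)
            assert all(r.bremer == 0 for r in recs)

    def test_censoring_when_nothing_contradicts(self):
        tree = random_binary_tree([f"t{i}" for i in range(6)],
                                  random.Random(1))
        m = congruent_matrix(tree, copies=10)  # decay = 10 per split
        mpts = branch_and_bound(m)
        splits = sorted(tree_bipartitions(tree), key=lambda b: b.members)
        recs = bremer_support(m, mpts, margin=3,
                              config=SearchConfig(max_saved_trees=100000))
        assert all(r.bremer_censored_at == 3 for r in recs)
        assert all(r.bremer_display == ">3" for r in recs)
        assert all(r.bremer_at_least(3) for r in recs)

    def test_monotone_in_margin(self):
        rng = random.Random(13)
        m = random_matrix(rng, 6, 14, max_state=1)
        mpts = branch_and_bound(m)
        cons = strict_consensus(mpts.optimal_trees())
        splits = sorted(tree_bipartitions(cons), key=lambda b: b.members)
        if not splits:
            return
        small = bremer_support(m, mpts, margin=1,
                               config=SearchConfig(max_saved_trees=100000))
        big = bremer_support(m, mpts, margin=5,
                             config=SearchConfig(max_saved_trees=100000))
        for s, b in zip(small, big):
            s_low = (s.bremer if s.bremer is not None
                     else s.bremer_censored_at + 1)
            b_low = (b.bremer if b.bremer is not None
                     else b.bremer_censored_at + 1)
            assert b_low >= s_low
            if b.bremer is not None:
                assert b.bremer <= 5


class TestRobustClades:
    def _records(self, uni, pairs):
        splits, recs = [], []
        for side, val in pairs:
            b = Bipartition(frozenset(uni), frozenset(side))
            splits.append(b)
            if isinstance(val, str):  # ">k"
                recs.append(SupportRecord(
                    b, bremer_censored_at=int(val[1:])))
            else:
                recs.append(SupportRecord(b, bremer=val))
        return splits, recs

    def test_threshold_rule(self):
        uni = "ABCDEFGH"
        s1, r1 = self._records(uni, [("AB", 3), ("CD", 3), ("EF", 3)])
        s2, r2 = self._records(uni, [("AB", 3), ("CD", 2), ("GH", 5)])
        kept = robust_clades(s1, r1, s2, r2, threshold=3)
        assert kept == [Bipartition(frozenset(uni), frozenset("AB"))]

    def test_censored_counts_as_at_least(self):
        uni = "ABCDEF"
        s1, r1 = self._records(uni, [("AB", ">3")])
        s2, r2 = self._records(uni, [("AB", 4)])
        assert robust_clades(s1, r1, s2, r2, threshold=3) == s1

    def test_threshold_zero_keeps_all_shared(self):
        uni = "ABCDEF"
        s1, r1 = self._records(uni, [("AB", 0), ("CD", 1)])
        kept = robust_clades(s1, r1, s1, r1, threshold=0)
        assert set(kept) == set(s1)

    def test_split_missing_from_one_analysis_dropped(self):
        uni = "ABCDEF"
        s1, r1 = self._records(uni, [("AB", 5), ("CD", 5)])
        s2, r2 = self._records(uni, [("AB", 5)])
        assert robust_clades(s1, r1, s2, r2) == [
            Bipartition(frozenset(uni), frozenset("AB"))]

    def test_comparison_on_shared_taxa(self):
        # different 6-taxon universes sharing 5 taxa; the {A,B} clade is
        # compared after restriction to the shared taxa
        u1, u2 = "ABCDEX", "ABCDEY"
        s1, r1 = self._records(u1, [("AB", 3)])
        s2, r2 = self._records(u2, [("AB", 3)])
        kept = robust_clades(s1, r1, s2, r2, threshold=3)
        assert kept == [Bipartition(frozenset("ABCDE"), frozenset("AB"))]


def test_support_table_format():
    b = Bipartition(frozenset("ABCDE"), frozenset("AB"))
    text = support_table([SupportRecord(b, bootstrap_pct=87.5, bremer=2),
                          SupportRecord(b, bremer_censored_at=3)])
    lines = text.strip().splitlines()
    assert lines[0] == "split_id\tmember_taxa\tbootstrap_pct\tbremer"
    assert lines[1] == "s1\tA,B\t87.5\t2"
    assert lines[2] == "s2\tA,B\t\t>3"
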