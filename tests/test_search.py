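import random

import pytest
from hypothesis import given, settings, strategies as st

from morphoclad.fitch import Encoding, tree_length
from morphoclad.matrix import parse_matrix
from morphoclad.search import (GuardError, SearchConfig, TreeSet,
                               branch_and_bound, canonical_key,
                               enumerate_rearrangements, heuristic_search)
from morphoclad.simulate import SimulationConfig, simulate_characters, simulate_tree
from morphoclad.tree import Tree, TreeError, all_topologies, random_binary_tree

from helpers import brute_force_spr_neighbors, exhaustive_minimum, random_matrix


class TestCanonicalKey:
    def test_rotation_and_rooting_invariance(self):
        taxa = ("A", "B", "C", "D")
        forms = ["((A,B),(C,D));", "((B,A),(D,C));", "(A,(B,(C,D)));",
                 "((C,D),(A,B));"]
        keys = {canonical_key(Tree.from_newick(s, taxa=taxa)) for s in forms}
        assert len(keys) == 1

    def test_different_topologies_differ(self):
        taxa = ("A", "B", "C", "D")
        a = canonical_key(Tree.from_newick("((A,B),(C,D));", taxa=taxa))
        b = canonical_key(Tree.from_newick("((A,C),(B,D));", taxa=taxa))
        assert a != b

    def test_all_105_six_leaf_keys_distinct(self):
        keys = {canonical_key(t) for t in all_topologies(list("ABCDEF"))}
        assert len(keys) == 105


class TestRearrangements:
    def test_nni_count_and_four_taxon_case(self):
        taxa = ("A", "B", "C", "D")
        t = Tree.from_newick("((A,B),(C,D));", taxa=taxa)
        nni = list(enumerate_rearrangements(t, "nni"))
        assert len(nni) == 2  # 2(n-3)
        assert {x.splits() for x in nni} == {
            Tree.from_newick("((A,C),(B,D));", taxa=taxa).splits(),
            Tree.from_newick("((A,D),(B,C));", taxa=taxa).splits()}

    @given(seed=st.integers(0, 10**6), n=st.integers(5, 9))
    @settings(max_examples=15)
    def test_nni_count_is_2n_minus_6(self, seed, n):
        t = random_binary_tree([f"t{i}" for i in range(n)],
                               random.Random(seed))
        assert sum(1 for _ in enumerate_rearrangements(t, "nni")) == 2 * (n - 3)

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=15)
    def test_neighborhood_nesting(self, seed):
        t = random_binary_tree([f"t{i}" for i in range(7)],
                               random.Random(seed))
        nni = {x.splits() for x in enumerate_rearrangements(t, "nni")}
        spr = {x.splits() for x in enumerate_rearrangements(t, "spr")}
        tbr = {x.splits() for x in enumerate_rearrangements(t, "tbr")}
        assert nni <= spr <= tbr
        assert t.splits() not in tbr

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=15)
    def test_spr_neighborhood_equals_brute_force(self, seed):
        t = random_binary_tree(list("ABCDEF"), random.Random(seed))
        got = {x.splits() for x in enumerate_rearrangements(t, "spr")}
        assert got == brute_force_spr_neighbors(t)

    def test_small_trees_rejected(self):
        with pytest.raises(TreeError):
            list(enumerate_rearrangements(
                Tree.from_newick("(A,(B,C));"), "tbr"))


class TestTreeSet:
    def test_deduplicates_by_splits(self):
        taxa = ("A", "B", "C", "D")
        ts = TreeSet()
        assert ts.add(Tree.from_newick("((A,B),(C,D));", taxa=taxa), 5)
        assert not ts.add(Tree.from_newick("((B,A),(D,C));", taxa=taxa), 5)
        assert len(ts) == 1

    def test_margin_pruning_on_new_optimum(self):
        taxa = ("A", "B", "C", "D")
        ts = TreeSet(keep_margin=1)
        ts.add(Tree.from_newick("((A,B),(C,D));", taxa=taxa), 7)
        ts.add(Tree.from_newick("((A,C),(B,D));", taxa=taxa), 6)
        assert len(ts) == 2  # 7 is within best+1
        ts.add(Tree.from_newick("((A,D),(B,C));", taxa=taxa), 4)
        assert ts.best_length == 4
        assert len(ts) == 1  # both older trees now exceed best+margin
        assert all(L <= ts.best_length + ts.keep_margin
                   for _, L in ts.items())

    def test_rejects_beyond_margin(self):
        taxa = ("A", "B", "C", "D")
        ts = TreeSet(keep_margin=0)
        ts.add(Tree.from_newick("((A,B),(C,D));", taxa=taxa), 3)
        assert not ts.add(Tree.from_newick("((A,C),(B,D));", taxa=taxa), 4)


class TestBranchAndBound:
    def test_four_taxon_single_informative_character(self):
        m = parse_matrix("A 0\nB 0\nC 1\nD 1", dialect="simple")
        ts = branch_and_bound(m)
        assert ts.best_length == 1
        assert [t.splits() for t in ts.optimal_trees()] == [
            Tree.from_newick("((A,B),(C,D));", taxa=m.taxa).splits()]

    def test_guard_refuses_fixture(self, bundled):
        with pytest.raises(GuardError, match="override"):
            branch_and_bound(bundled)

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=10)
    def test_equals_exhaustive_enumeration(self, seed):
        rng = random.Random(seed)
        n = rng.randrange(5, 8)
        m = random_matrix(rng, n, 8, max_state=rng.randrange(1, 3),
                          p_missing=0.15, p_polymorphic=0.1)
        ts = branch_and_bound(m)
        best, keys = exhaustive_minimum(m)
        assert ts.best_length == best
        assert {t.splits() for t in ts.optimal_trees()} == keys

    def test_result_independent_of_taxon_order(self):
        rng = random.Random(11)
        m = random_matrix(rng, 6, 10, max_state=1)
        from morphoclad.matrix import subset_taxa
        perm = list(m.taxa)
        rng.shuffle(perm)
        a = branch_and_bound(m)
        b = branch_and_bound(subset_taxa(m, perm))

        def renamed(keys, taxa):
            out = set()
            for k in keys:
                out.add(frozenset(
                    frozenset(taxa[i] for i in range(len(taxa))
                              if (mask >> i) & 1) for mask in k))
            return out

        assert a.best_length == b.best_length
        got_a = renamed([t.splits() for t in a.optimal_trees()], m.taxa)
        got_b = renamed([t.splits() for t in b.optimal_trees()], tuple(perm))

        def both_sides(groups, taxa):
            full = frozenset(taxa)
            return {frozenset(frozenset({s, full - s})
                              for s in k) for k in groups}

        assert both_sides(got_a, m.taxa) == both_sides(got_b, m.taxa)


class TestHeuristicSearch:
    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=8)
    def test_matches_exact_search_on_small_matrices(self, seed):
        rng = random.Random(seed)
        m = random_matrix(rng, 7, 12, max_state=2, p_missing=0.1)
        ts = heuristic_search(m, SearchConfig(n_starts=5, swap="tbr",
                                              seed=seed))
        exact = branch_and_bound(m)
        assert ts.best_length == exact.best_length
        assert ({t.splits() for t in ts.optimal_trees()}
                == {t.splits() for t in exact.optimal_trees()})

    def test_deterministic_under_fixed_seed(self):
        rng = random.Random(2)
        m = random_matrix(rng, 9, 20, max_state=2, p_missing=0.1)
        a = heuristic_search(m, SearchConfig(n_starts=4, swap="spr", seed=9))
        b = heuristic_search(m, SearchConfig(n_starts=4, swap="spr", seed=9))
        assert a.best_length == b.best_length
        assert ({t.splits() for t in a.trees}
                == {t.splits() for t in b.trees})

    def test_closure_property(self):
        # every TBR neighbour of every reported MPT is either longer or in
        # the set
        sim = simulate_tree(SimulationConfig(n_taxa=9, seed=4))
        m = simulate_characters(sim, SimulationConfig(
            n_taxa=9, n_characters=25, substitution_rate=0.5, seed=4))
        ts = heuristic_search(m, SearchConfig(n_starts=5, swap="tbr", seed=0))
        enc = Encoding(m)
        saved = {t.splits() for t in ts.optimal_trees()}
        for t in ts.optimal_trees():
            for nb in enumerate_rearrangements(t, "tbr", m):
                L = tree_length(nb, enc)
                assert L > ts.best_length or nb.splits() in saved

    def test_keep_margin_retains_suboptimal_trees(self):
        rng = random.Random(8)
        m = random_matrix(rng, 7, 10, max_state=1, p_missing=0.1)
        ts = heuristic_search(m, SearchConfig(n_starts=5, swap="tbr", seed=1,
                                              keep_margin=2,
                                              max_saved_trees=500))
        lengths = sorted(L for _, L in ts.items())
        assert lengths[0] == ts.best_length
        assert all(L <= ts.best_length + 2 for L in lengths)
        assert len(ts) >= len(ts.optimal_trees())

    def test_too_few_taxa_rejected(self):
        m = parse_matrix("A 0\nB 0\nC 1", dialect="simple")
        with pytest.raises(TreeError):
            heuristic_search(m, SearchConfig(n_starts=1))
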