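"""Wagner parsimony: length, search, rooting, fit indices, bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gontogeny import (
    PhyloTree,
    bootstrap_support,
    enumerate_topologies,
    fit_indices,
    from_newick,
    heuristic_search,
    lundberg_root,
    max_state_ancestor,
    sankoff_length,
    strict_consensus,
    wagner_length,
    zero_ancestor,
)

from conftest import ladder_states, random_states


def tree_of(newick: str) -> PhyloTree:
    return from_newick(newick)


class TestWagnerLength:
    def test_constant_character_is_zero(self):
        states = pd.DataFrame({"c": [5, 5, 5, 5]}, index=list("ABCD"))
        for t in enumerate_topologies(list("ABCD")):
            assert wagner_length(t, states) == 0

    def test_four_taxon_worked_example(self):
        states = pd.DataFrame({"c": [0, 2, 1, 3]}, index=list("ABCD"))
        assert wagner_length(tree_of("((A,B),(C,D));"), states) == 4

    def test_three_leaf_star_is_median_deviation(self):
        states = pd.DataFrame({"c": [0, 1, 5]}, index=list("XYZ"))
        assert wagner_length(PhyloTree.from_labels(["X", "Y", "Z"]), states) == 5

    def test_two_leaf_distance(self):
        states = pd.DataFrame({"c": [3, 9]}, index=list("AB"))
        assert wagner_length(PhyloTree.from_labels(["A", "B"]), states) == 6

    def test_leaf_character_mismatch_is_error(self):
        states = pd.DataFrame({"c": [0, 1]}, index=list("AB"))
        with pytest.raises(ValueError, match="without character"):
            wagner_length(tree_of("((A,B),(C,D));"), states)

    def test_invariant_under_leaf_permutation_and_rerooting(self, rng):
        for _ in range(25):
            S = random_states(rng, 6, 4, max_state=9)
            t = next(
                itertools.islice(
                    enumerate_topologies(list(S.index)), int(rng.integers(0, 105)), None
                )
            )
            base = wagner_length(t, S)
            # re-rooting: place a root on any edge; length must not change
            for edge in t.edges()[:4]:
                rt = t.copy()
                rt.root_on_edge(edge)
                assert wagner_length(rt, S) == base
            # leaf relabelling permutation applied to both tree and matrix
            perm = rng.permutation(list(S.index))
            relabel = dict(zip(S.index, perm))
            t2 = t.copy()
            t2.labels = {n: relabel[l] for n, l in t.labels.items()}
            S2 = S.rename(index=relabel)
            assert wagner_length(t2, S2) == base


class TestSankoffAgreement:
    def test_two_leaf_forced(self):
        states = pd.DataFrame({"c": [3, 9]}, index=list("AB"))
        assert sankoff_length(PhyloTree.from_labels(["A", "B"]), states) == 6

    def test_constant_character(self):
        states = pd.DataFrame({"c": [4, 4, 4]}, index=list("ABC"))
        assert sankoff_length(PhyloTree.from_labels(list("ABC")), states) == 0

    def test_agreement_on_1000_random_instances(self, rng):
        # the headline equivalence: Farris intervals == Sankoff DP
        for i in range(1000):
            n = int(rng.integers(4, 9))
            S = random_states(rng, n, int(rng.integers(1, 5)), max_state=31)
            topos = list(enumerate_topologies(list(S.index[:n])))
            t = topos[int(rng.integers(len(topos)))] if n <= 6 else None
            if t is None:
                t = heuristic_search(S, n_addition_sequences=1, seed=i, tbr=False).best
            assert wagner_length(t, S) == sankoff_length(t, S)

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_agreement_property(self, data):
        n = data.draw(st.integers(4, 6))
        labels = [f"t{i}" for i in range(n)]
        rows = data.draw(
            st.lists(
                st.lists(st.integers(0, 31), min_size=3, max_size=3),
                min_size=n,
                max_size=n,
            )
        )
        S = pd.DataFrame(rows, index=labels)
        topos = list(enumerate_topologies(labels))
        idx = data.draw(st.integers(0, len(topos) - 1))
        t = topos[idx]
        assert wagner_length(t, S) == sankoff_length(t, S)


class TestHeuristicSearch:
    def test_fewer_than_four_taxa_returns_unique_topology(self):
        S = pd.DataFrame({"c": [0, 9, 5]}, index=list("ABC"))
        res = heuristic_search(S)
        assert len(res.trees) == 1 and res.length == 9

    def test_ladder_matrix_recovers_generating_topology(self):
        S = ladder_states("ABCDE")
        res = heuristic_search(S, n_addition_sequences=5, seed=0)
        # homoplasy-free: TL equals the sum of character ranges
        assert res.length == 4 * 3 * 8
        expected = tree_of("(A,(B,(C,(D,E))));").bipartitions()
        assert res.best.bipartitions() == expected

    @pytest.mark.parametrize("n_taxa,n_chars,seed", [
        (5, 3, 0), (5, 6, 1), (6, 3, 2), (6, 5, 3), (7, 3, 4), (7, 4, 5),
    ])
    def test_attains_exhaustive_optimum(self, n_taxa, n_chars, seed):
        rng = np.random.default_rng(seed)
        S = random_states(rng, n_taxa, n_chars, max_state=15)
        res = heuristic_search(S, n_addition_sequences=5, seed=seed)
        optimum = min(
            wagner_length(t, S) for t in enumerate_topologies(list(S.index))
        )
        assert res.length == optimum

    def test_tbr_never_worse_than_stepwise(self, rng):
        S = random_states(rng, 8, 5)
        plain = heuristic_search(S, n_addition_sequences=2, seed=7, tbr=False)
        refined = heuristic_search(S, n_addition_sequences=2, seed=7, tbr=True)
        assert refined.length <= plain.length

    def test_duplicate_rows_yield_zero_length_pair(self):
        S = pd.DataFrame(
            [[0, 0], [0, 0], [9, 9], [5, 1]], index=list("ABCD")
        )
        res = heuristic_search(S, n_addition_sequences=3, seed=0)
        assert frozenset("AB") in res.best.bipartitions() | {frozenset("AB")}
        assert res.length == wagner_length(res.best, S)

    def test_deterministic_given_seed(self, rng):
        S = random_states(rng, 7, 4)
        a = heuristic_search(S, n_addition_sequences=3, seed=11)
        b = heuristic_search(S, n_addition_sequences=3, seed=11)
        assert [t.to_newick() for t in a.trees] == [t.to_newick() for t in b.trees]

    def test_strict_consensus_of_cooptimal_trees(self):
        # two characters in conflict produce co-optimal topologies
        S = pd.DataFrame([[0, 0], [0, 9], [9, 0], [9, 9]], index=list("ABCD"))
        res = heuristic_search(S, n_addition_sequences=10, seed=0)
        cons = strict_consensus(res.trees)
        assert cons.leaf_labels() == set("ABCD")


class TestLundbergRooting:
    def test_ladder_tof_root_adjacent_to_max_state_taxon(self):
        S = ladder_states("ABCDE")  # E holds the maximum state everywhere
        res = heuristic_search(S, n_addition_sequences=3, seed=0)
        rooting = lundberg_root(res.best, S, max_state_ancestor(S))
        root_neighbors = {
            rooting.tree.labels.get(n) for n in rooting.tree.adj[rooting.tree.root]
        }
        assert "E" in root_neighbors

    def test_rooted_length_is_unrooted_plus_attachment(self, rng):
        S = random_states(rng, 6, 4)
        res = heuristic_search(S, n_addition_sequences=2, seed=3)
        rooting = lundberg_root(res.best, S, max_state_ancestor(S))
        assert rooting.attachment_cost >= 0
        assert rooting.rooted_length == res.length + rooting.attachment_cost

    def test_exhaustive_attachment_scan(self, rng):
        # oracle: attach the ancestor on every edge and recompute from scratch
        S = random_states(rng, 6, 3)
        res = heuristic_search(S, n_addition_sequences=2, seed=5)
        anc = max_state_ancestor(S)
        S2 = pd.concat([S, pd.DataFrame([anc], index=["ANC"])])
        best = None
        for edge in res.best.edges():
            t = res.best.copy()
            t.insert_leaf(edge, "ANC")
            l = wagner_length(t, S2)
            best = l if best is None else min(best, l)
        rooting = lundberg_root(res.best, S, anc)
        assert rooting.rooted_length == best

    def test_symmetric_matrix_reports_ties(self):
        S = pd.DataFrame([[0], [0], [9], [9]], index=list("ABCD"))
        res = heuristic_search(S, n_addition_sequences=3, seed=0)
        rooting = lundberg_root(res.best, S, np.array([9]))
        assert len(rooting.tied_edges) >= 2
        assert rooting.edge == rooting.tied_edges[0]

    def test_tol_mode_roots_next_to_all_zero_taxon(self):
        S = pd.DataFrame(
            [[0, 0, 0], [3, 2, 1], [6, 5, 4], [9, 9, 9], [9, 8, 9]],
            index=list("ZBCDE"),
        )
        res = heuristic_search(S, n_addition_sequences=3, seed=0)
        rooting = lundberg_root(res.best, S, zero_ancestor(S))
        root_neighbors = {
            rooting.tree.labels.get(n) for n in rooting.tree.adj[rooting.tree.root]
        }
        assert "Z" in root_neighbors


class TestFitIndices:
    def test_homoplasy_free_ladder(self):
        S = ladder_states("ABCDE")
        t = tree_of("(A,(B,(C,(D,E))));")
        fit = fit_indices(t, S)
        assert fit.ci == 1.0 and fit.ri == 1.0 and fit.hi == 0.0
        assert (fit.per_character_hi == 0).all()

    def test_four_taxon_hand_computation(self):
        S = pd.DataFrame({"c": [0, 2, 1, 3]}, index=list("ABCD"))
        fit = fit_indices(tree_of("((A,B),(C,D));"), S)
        assert fit.min_steps.tolist() == [3]
        assert fit.obs_steps.tolist() == [4]
        assert fit.max_steps.tolist() == [4]
        assert fit.ci == pytest.approx(0.75)
        assert fit.ri == 0.0
        assert fit.per_character_hi[0] == pytest.approx(0.25)

    def test_ensemble_equals_stepwise_aggregation(self, rng):
        S = random_states(rng, 6, 5)
        t = heuristic_search(S, n_addition_sequences=2, seed=9).best
        fit = fit_indices(t, S)
        assert fit.ci == pytest.approx(fit.min_steps.sum() / fit.obs_steps.sum())
        assert fit.ri == pytest.approx(
            (fit.max_steps.sum() - fit.obs_steps.sum())
            / (fit.max_steps.sum() - fit.min_steps.sum())
        )
        assert fit.hi == pytest.approx(1 - fit.ci)

    def test_constant_matrix_ri_undefined(self):
        S = pd.DataFrame([[4], [4], [4], [4]], index=list("ABCD"))
        fit = fit_indices(tree_of("((A,B),(C,D));"), S)
        assert fit.ri is None and fit.ci == 1.0


class TestBootstrap:
    def test_perfect_characters_give_full_support(self):
        S = ladder_states("ABCDEF", step=2, n_chars=20)
        res = heuristic_search(S, n_addition_sequences=2, seed=0)
        support = bootstrap_support(S, res.best, n_reps=30, seed=4)
        assert support and all(pct == 100.0 for pct in support.values())

    def test_seeded_run_is_reproducible(self, rng):
        S = random_states(rng, 6, 6)
        ref = heuristic_search(S, n_addition_sequences=2, seed=0).best
        a = bootstrap_support(S, ref, n_reps=10, seed=2)
        b = bootstrap_support(S, ref, n_reps=10, seed=2)
        assert a == b

    def test_single_character_supports_only_its_splits(self):
        # one character splitting {A,B} (state 0) from {C,D,E} (state 9)
        S = pd.DataFrame({"c": [0, 0, 9, 9, 9]}, index=list("ABCDE"))
        ref = tree_of("((A,B),(C,(D,E)));")
        support = bootstrap_support(S, ref, n_reps=20, seed=0)
        implied = frozenset("CDE") if "A" == min("ABCDE") else frozenset("AB")
        for split, pct in support.items():
            if split == implied:
                assert pct == 100.0
            else:
                assert pct < 100.0
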