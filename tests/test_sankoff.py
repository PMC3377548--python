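"""Network Sankoff: tables, bounds, conflicts, and the majority heuristic."""

import numpy as np
import pytest

from netparsimony import (
    CostMatrix,
    GeneratorConfig,
    LeafAssignment,
    NetworkError,
    brute_force_score,
    evaluate_p2,
    exact_score,
    majority_upper_bound,
    random_characters,
    random_network,
    sankoff_bounds,
    sankoff_post_order,
    sankoff_pre_order,
    sankoff_tree,
)

UNIT2 = CostMatrix.unit(2)
SITE_L = {1: 0, 2: 0, 3: 1, 4: 1}


class TestPostOrderTables:
    def test_cherry_three_states(self, cherry):
        tables = sankoff_post_order(cherry, {1: 0, 2: 1}, CostMatrix.unit(3))
        assert tables.S[0].tolist() == [1.0, 1.0, 2.0]

    def test_fig1l_hand_derived_tables(self, fig1l):
        """Hand-executing the recursion: the non-traversal parent 7 prices
        edge (7, 8) at min_j c_ij = 0, giving S_7 = (1, 0) and finally
        S_root = (2, 1)."""
        tables = sankoff_post_order(fig1l, SITE_L, UNIT2)
        assert tables.S[8].tolist() == [0.0, 1.0]
        assert tables.S[7].tolist() == [1.0, 0.0]
        assert tables.S[6].tolist() == [0.0, 2.0]
        assert tables.S[0].tolist() == [2.0, 1.0]

    def test_eq1_consistency(self, fig1l):
        """S_v(i) equals the sum of its per-child edge contributions."""
        tables = sankoff_post_order(fig1l, SITE_L, UNIT2)
        for v in fig1l.vertices:
            if fig1l.out_degree(v) == 0:
                continue
            total = sum(tables.s[(v, w)] for w in fig1l.children(v))
            assert np.array_equal(tables.S[v], total)

    def test_tree_specialization(self):
        """On a tree the network tables equal classic Sankoff."""
        tree = random_network(GeneratorConfig(n=6, r=0, seed=3, k=3))
        site = random_characters(tree, 3, 1, 4).site(0)
        cost = CostMatrix.unit(3)
        res = sankoff_bounds(tree, site, cost)
        classic_score, classic_ext = sankoff_tree(tree, site, cost)
        assert res.lower == res.upper == classic_score
        assert res.conflicts == []
        assert res.extension == classic_ext

    def test_leaf_state_outside_alphabet(self, cherry):
        with pytest.raises(NetworkError):
            sankoff_post_order(cherry, {1: 0, 2: 5}, UNIT2)

    def test_unassigned_leaf(self, cherry):
        with pytest.raises(NetworkError):
            sankoff_post_order(cherry, {1: 0}, UNIT2)


class TestPreOrderBounds:
    def test_fig1l_bounds_and_conflict(self, fig1l):
        """The two parents of reticulation 8 backtrack different states:
        lower bound 1, one conflict, upper bound 2 — which brackets the
        true optimum 2."""
        res = sankoff_bounds(fig1l, SITE_L, UNIT2)
        assert res.lower == 1.0
        assert res.upper == 2.0
        assert len(res.conflicts) == 1
        assert res.conflicts[0].vertex == 8
        assert brute_force_score(fig1l, SITE_L, UNIT2).score == 2.0

    def test_upper_equals_p2_of_extension(self, fig1l):
        res = sankoff_bounds(fig1l, SITE_L, UNIT2)
        assert res.upper == evaluate_p2(fig1l, res.extension, UNIT2)

    def test_extension_agrees_with_leaves(self, fig1l):
        res = sankoff_bounds(fig1l, SITE_L, UNIT2)
        for leaf in fig1l.leaves:
            assert res.extension[leaf] == SITE_L[fig1l.label_of(leaf)]

    def test_sandwich_on_corpus(self, small_corpus):
        """Lower bound <= exact optimum <= upper bound on every instance,
        the upper bound equals the extension's edge-sum, and no conflict
        implies the bounds coincide."""
        for inst in small_corpus:
            res = sankoff_bounds(inst.net, inst.site, inst.cost)
            opt = brute_force_score(inst.net, inst.site, inst.cost).score
            assert res.lower <= opt + 1e-9, inst.tag
            assert opt <= res.upper + 1e-9, inst.tag
            assert res.upper == pytest.approx(
                evaluate_p2(inst.net, res.extension, inst.cost)
            ), inst.tag
            if not inst.net.reticulations or not res.conflicts:
                assert res.lower == pytest.approx(res.upper), inst.tag

    def test_conflict_occurs_somewhere(self, small_corpus):
        assert any(
            sankoff_bounds(i.net, i.site, i.cost).conflicts
            for i in small_corpus
            if i.net.r > 0
        )


class TestEvaluateP2:
    def test_cherry_values(self, cherry):
        assert evaluate_p2(cherry, {0: 0, 1: 0, 2: 0}, UNIT2) == 0
        assert evaluate_p2(cherry, {0: 0, 1: 0, 2: 1}, UNIT2) == 1

    def test_fig1l_edge_loop_oracle(self, fig1l):
        # changes on (0,4), (5,7) and (7,8) only
        ext = {0: 0, 4: 1, 5: 0, 6: 0, 1: 0, 8: 0, 2: 0, 7: 1, 3: 1}
        hand = sum(
            UNIT2.costs[ext[u], ext[v]] for (u, v) in fig1l.edges
        )
        assert evaluate_p2(fig1l, ext, UNIT2) == hand == 3

    def test_missing_vertex_raises(self, cherry):
        with pytest.raises(NetworkError):
            evaluate_p2(cherry, {0: 0, 1: 0}, UNIT2)


class TestMissingData:
    def test_missing_leaf_is_free(self, cherry):
        res = sankoff_bounds(cherry, {1: 0, 2: None}, UNIT2)
        assert res.lower == res.upper == 0.0
        assert res.extension[2] == 0

    def test_leaf_assignment_round_trip(self):
        chars = LeafAssignment.from_symbols(
            {1: ["0", "?"], 2: ["1", "1"]}, ["0", "1"]
        )
        assert chars.sites == 2
        assert chars.site(0) == {1: 0, 2: 1}
        assert chars.site(1) == {1: None, 2: 1}


class TestEdgeWeights:
    def test_weight_scales_edge_cost(self, cherry):
        site = {1: 0, 2: 1}
        plain = sankoff_bounds(cherry, site, UNIT2)
        weighted = sankoff_bounds(
            cherry, site, UNIT2, edge_weights={(0, 2): 3.0}
        )
        # a change is forced on exactly one root edge; tripling the cost of
        # (0, 2) makes the change happen on (0, 1) instead
        assert plain.lower == 1.0
        assert weighted.lower == 1.0
        assert weighted.extension[0] == 1

    def test_negative_weight_rejected(self, cherry):
        with pytest.raises(ValueError):
            sankoff_bounds(
                cherry, {1: 0, 2: 1}, UNIT2, edge_weights={(0, 1): -1.0}
            )


class TestMajorityUpperBound:
    def test_tree_gives_optimum(self):
        tree = random_network(GeneratorConfig(n=5, r=0, seed=9))
        site = random_characters(tree, 2, 1, 10).site(0)
        ub, _ = majority_upper_bound(tree, site, UNIT2)
        assert ub == sankoff_tree(tree, site, UNIT2)[0]

    def test_fig1l_pins_to_reachable_leaf(self, fig1l):
        # reticulation 8 reaches only leaf 2 (state 0), so it is pinned to 0
        ub, ext = majority_upper_bound(fig1l, SITE_L, UNIT2)
        assert ext[8] == 0
        assert ub == 2.0

    def test_upper_bounds_optimum_on_corpus(self, small_corpus):
        for inst in small_corpus:
            ub, ext = majority_upper_bound(inst.net, inst.site, inst.cost)
            opt = brute_force_score(inst.net, inst.site, inst.cost).score
            assert opt <= ub + 1e-9, inst.tag
            assert ub == pytest.approx(
                evaluate_p2(inst.net, ext, inst.cost)
            ), inst.tag
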