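"""Displayed trees, P1 scoring, and the classic tree algorithms."""

import itertools

import dendropy
import pytest

from netparsimony import (
    CostMatrix,
    GeneratorConfig,
    NetworkError,
    display_tree,
    enumerate_displayed_trees,
    fitch_tree,
    random_characters,
    random_cost_matrix,
    random_network,
    sankoff_tree,
    score_p1_exhaustive,
    to_newick,
)

UNIT2 = CostMatrix.unit(2)


class TestDisplayTree:
    def test_fig1l_retain_first_parent(self, fig1l):
        dt = display_tree(fig1l, {8: (6, 8)})
        assert dt.tree.edges == [(0, 4), (0, 5), (5, 3), (5, 6), (6, 1), (6, 2)]
        removed = {v for v, _ in dt.contraction_log}
        assert removed == {7, 8}

    def test_fig1l_retain_second_parent(self, fig1l):
        # removing (6, 8) cascades: 6 drops to outdegree one and is
        # suppressed as well
        dt = display_tree(fig1l, {8: (7, 8)})
        assert dt.tree.edges == [(0, 4), (0, 5), (5, 1), (5, 7), (7, 2), (7, 3)]

    def test_tree_input_identity(self, cherry):
        dt = display_tree(cherry, {})
        assert dt.tree.edges == cherry.edges
        assert dt.contraction_log == []

    def test_sister_reticulations_rejected(self, fig1r):
        with pytest.raises(NetworkError, match="sister"):
            display_tree(fig1r, {})

    def test_incomplete_choice_rejected(self, fig1l):
        with pytest.raises(NetworkError):
            display_tree(fig1l, {})
        with pytest.raises(NetworkError):
            display_tree(fig1l, {8: (5, 8)})


class TestEnumeration:
    def test_fig1l_has_two_trees(self, fig1l):
        assert len(enumerate_displayed_trees(fig1l)) == 2 == 2**fig1l.r

    def test_cherry_displays_itself(self, cherry):
        trees = enumerate_displayed_trees(cherry)
        assert len(trees) == 1
        assert trees[0].tree.edges == cherry.edges

    def test_two_reticulations_give_four_trees(self):
        net = random_network(
            GeneratorConfig(n=5, r=2, seed=11, require_no_sister=True)
        )
        trees = enumerate_displayed_trees(net)
        assert len(trees) == 4
        for dt in trees:
            assert dt.tree.leaves == net.leaves
            # binary tree on n leaves: n - 1 internal vertices
            assert len(dt.tree.vertices) == 2 * net.n - 1

    def test_counts_on_corpus(self, no_sister_corpus):
        for inst in no_sister_corpus:
            trees = enumerate_displayed_trees(inst.net)
            assert len(trees) == 2**inst.net.r, inst.tag
            assert all(dt.tree.leaves == inst.net.leaves for dt in trees), inst.tag

    def test_newick_output_parses(self, fig1l):
        for dt in enumerate_displayed_trees(fig1l):
            nwk = to_newick(dt.tree)
            tree = dendropy.Tree.get(data=nwk, schema="newick")
            assert sorted(
                int(t.label) for t in tree.taxon_namespace
            ) == sorted(fig1l.leaf_labels.values())


def _brute_force_tree_score(tree, site, cost):
    """Independent oracle: enumerate all internal assignments."""
    internal = [v for v in tree.vertices if tree.out_degree(v) > 0]
    k = cost.k
    best = float("inf")
    for states in itertools.product(range(k), repeat=len(internal)):
        ext = dict(zip(internal, states))
        ext.update({v: site[tree.label_of(v)] for v in tree.leaves})
        score = sum(cost.costs[ext[u], ext[v]] for (u, v) in tree.edges)
        best = min(best, score)
    return best


class TestClassicTreeAlgorithms:
    def test_cherry_examples(self, cherry):
        assert sankoff_tree(cherry, {1: 0, 2: 0}, UNIT2)[0] == 0
        assert sankoff_tree(cherry, {1: 0, 2: 1}, UNIT2)[0] == 1
        assert fitch_tree(cherry, {1: 0, 2: 0})[0] == 0
        assert fitch_tree(cherry, {1: 0, 2: 1})[0] == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_sankoff_tree_matches_enumeration(self, seed):
        tree = random_network(GeneratorConfig(n=6, r=0, seed=seed))
        cost = random_cost_matrix(2, seed, "integer")
        site = random_characters(tree, 2, 1, seed + 50).site(0)
        score, ext = sankoff_tree(tree, site, cost)
        assert score == _brute_force_tree_score(tree, site, cost)
        assert score == sum(
            cost.costs[ext[u], ext[v]] for (u, v) in tree.edges
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_fitch_equals_unit_sankoff_on_trees(self, seed):
        tree = random_network(GeneratorConfig(n=7, r=0, seed=seed))
        k = 2 + seed % 3
        site = random_characters(tree, k, 1, seed + 80).site(0)
        count, _ = fitch_tree(tree, site)
        score, _ = sankoff_tree(tree, site, CostMatrix.unit(k))
        assert count == score

    def test_reticulate_input_rejected(self, fig1l):
        with pytest.raises(NetworkError):
            sankoff_tree(fig1l, {1: 0, 2: 0, 3: 1, 4: 1}, UNIT2)
        with pytest.raises(NetworkError):
            fitch_tree(fig1l, {1: 0, 2: 0, 3: 1, 4: 1})


class TestP1:
    def test_tree_input_is_classic_sankoff(self, cherry):
        site = {1: 0, 2: 1}
        assert score_p1_exhaustive(cherry, site, UNIT2)[0] == 1

    def test_fig1l_examples(self, fig1l):
        assert score_p1_exhaustive(fig1l, {1: 0, 2: 0, 3: 1, 4: 1}, UNIT2)[0] == 1
        assert score_p1_exhaustive(fig1l, {1: 0, 2: 1, 3: 0, 4: 1}, UNIT2)[0] == 2

    def test_p1_at_most_p2_under_unit_costs(self, no_sister_corpus):
        """P1 scores a displayed subtree of the network, so under unit
        costs it can never exceed the all-edges optimum."""
        from netparsimony import exact_score

        for inst in no_sister_corpus:
            p1 = score_p1_exhaustive(inst.net, inst.site, inst.cost)[0]
            p2 = exact_score(inst.net, inst.site, inst.cost).score
            assert p1 <= p2, inst.tag
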