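"""Network representation, classification and validation."""

import pytest

from netparsimony import (
    NetworkError,
    PhyloNetwork,
    Role,
    cannot_coexist,
    classify_vertex,
    has_sister_reticulations,
    validate_structure,
    validate_time_consistency,
)


class TestClassify:
    @pytest.mark.parametrize(
        "vertex, role",
        [
            (0, Role.ROOT),
            (5, Role.INTERNAL_TREE),
            (6, Role.INTERNAL_TREE),
            (8, Role.RETICULATE),
            (2, Role.LEAF),
        ],
    )
    def test_fig1l_roles(self, fig1l, vertex, role):
        assert classify_vertex(fig1l, vertex) == role

    def test_cherry_root(self, cherry):
        assert classify_vertex(cherry, 0) == Role.ROOT

    def test_unknown_vertex_raises(self, cherry):
        with pytest.raises(NetworkError):
            classify_vertex(cherry, 99)

    def test_disallowed_degree_raises(self):
        net = PhyloNetwork([(0, 1), (0, 2), (0, 3)])
        with pytest.raises(NetworkError, match="signature"):
            classify_vertex(net, 0)

    def test_role_partition(self, fig1l):
        roles = [classify_vertex(fig1l, v) for v in fig1l.vertices]
        assert roles.count(Role.ROOT) == 1
        assert roles.count(Role.LEAF) == fig1l.n == 4
        assert roles.count(Role.RETICULATE) == fig1l.r == 1


class TestValidateStructure:
    def test_cherry_valid_all_tiers(self, cherry):
        rep = validate_structure(cherry)
        assert rep.is_valid()
        for tier in ("dag", "degrees", "edge_condition"):
            assert rep.is_valid(tier)

    def test_fig1l_vertex_count_identity(self, fig1l):
        assert validate_structure(fig1l).is_valid()
        assert len(fig1l.vertices) == 9 == 2 * (fig1l.n + fig1l.r) - 1

    def test_parallel_edge_rejected_at_construction(self):
        with pytest.raises(NetworkError, match="parallel"):
            PhyloNetwork([(0, 1), (0, 1), (0, 2)])

    def test_degree_violation_reported(self):
        net = PhyloNetwork([(0, 1), (0, 2), (0, 3)])
        rep = validate_structure(net)
        assert not rep.is_valid("degrees")
        assert any(rule == "degree_combination" for rule, _, _ in rep.violations)

    def test_bad_leaf_labels_reported(self):
        net = PhyloNetwork([(0, 7), (0, 9)])
        rep = validate_structure(net)
        assert any(rule == "leaf_label_bijection" for rule, _, _ in rep.violations)

    def test_edge_condition_violation_reported(self):
        # two reticulations in a chain share an edge with no tree endpoint
        edges = [
            (0, 4), (0, 5), (4, 6), (4, 7), (5, 7), (7, 8), (5, 8),
            (8, 1), (6, 2), (6, 3),
        ]
        net = PhyloNetwork(edges)
        rep = validate_structure(net)
        assert any(rule == "tree_endpoint" for rule, _, _ in rep.violations)


class TestCoexistence:
    def test_tree_ancestor_cannot_coexist(self, cherry):
        assert cannot_coexist(cherry, 0, 1)

    def test_fig1l_reticulation_parents_coexist(self, fig1l):
        assert not cannot_coexist(fig1l, 6, 7)
        assert not cannot_coexist(fig1l, 7, 6)

    def test_fig1l_ancestor_chain(self, fig1l):
        assert cannot_coexist(fig1l, 5, 2)

    def test_unknown_vertex_raises(self, fig1l):
        with pytest.raises(NetworkError):
            cannot_coexist(fig1l, 0, 42)


class TestTimeConsistency:
    def test_tree_trivially_consistent(self, cherry):
        assert validate_time_consistency(cherry).is_valid()

    def test_fig1l_consistent(self, fig1l):
        assert validate_time_consistency(fig1l).is_valid()

    def test_parent_child_reticulation_violates(self):
        # reticulation 7 has parents 5 and 6 joined by the tree edge (5, 6)
        net = PhyloNetwork(
            [(0, 5), (0, 3), (5, 6), (5, 7), (6, 7), (6, 2), (7, 1)]
        )
        assert validate_structure(net).is_valid()
        assert cannot_coexist(net, 5, 6)
        rep = validate_time_consistency(net)
        assert not rep.is_valid("time_consistency")
        assert rep.violations[0][1] == 7


class TestSisterReticulations:
    def test_fixtures(self, cherry, fig1l, fig1r):
        assert not has_sister_reticulations(cherry)
        assert not has_sister_reticulations(fig1l)
        assert has_sister_reticulations(fig1r)


class TestCorpusInvariants:
    def test_vertex_count_identity(self, small_corpus):
        for inst in small_corpus:
            net = inst.net
            assert len(net.vertices) == 2 * (net.n + net.r) - 1, inst.tag

    def test_reticulation_neighborhood(self, small_corpus):
        """Both parents of a reticulation are tree vertices; its child is a
        tree vertex or leaf (the edge condition)."""
        for inst in small_corpus:
            net = inst.net
            for w in net.reticulations:
                for p in net.parents(w):
                    assert not net.is_reticulate(p), inst.tag
                (child,) = net.children(w)
                assert not net.is_reticulate(child), inst.tag

    def test_structure_valid(self, small_corpus):
        for inst in small_corpus:
            assert validate_structure(inst.net).is_valid(), inst.tag
            assert validate_time_consistency(inst.net).is_valid(), inst.tag
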