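"""Rooted phylogenetic networks.

A phylogenetic network is a rooted directed acyclic graph in which every
vertex has one of four (indegree, outdegree) signatures:

* ``(0, 2)`` — the root,
* ``(1, 0)`` — a leaf,
* ``(1, 2)`` — an internal tree vertex,
* ``(2, 1)`` — a reticulate vertex (hybridization, recombination or
  horizontal transfer).

Vertices other than reticulate vertices are *tree vertices*; edges whose
head is a reticulate vertex are *reticulate edges*, all others *tree
edges*.  Structural validity additionally requires that every edge has at
least one tree-vertex endpoint, and time-consistency requires that the two
parents of every reticulate vertex can coexist in time (see
:func:`cannot_coexist`).

Leaves carry the taxon labels ``1..n``; by convention the leaf vertex ids
coincide with the labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "PhyloNetwork",
    "Role",
    "ValidationReport",
    "classify_vertex",
    "validate_structure",
    "cannot_coexist",
    "validate_time_consistency",
    "has_sister_reticulations",
    "NetworkError",
]

#: Allowed (indegree, outdegree) signatures.
ALLOWED_DEGREES = {(0, 2), (1, 0), (1, 2), (2, 1)}


class NetworkError(ValueError):
    """Raised for malformed networks or out-of-contract queries."""


class Role(str, Enum):
    ROOT = "root"
    LEAF = "leaf"
    INTERNAL_TREE = "internal_tree"
    RETICULATE = "reticulate"


class PhyloNetwork:
    """A rooted phylogenetic network over integer-labelled vertices.

    Parameters
    ----------
    edges:
        Iterable of ``(tail, head)`` pairs of nonnegative integers.
        Parallel edges are rejected: they would give an edge both of whose
        endpoints touch a reticulate head, and they break the uniqueness of
        the traversal tree.
    leaf_labels:
        Optional mapping from leaf vertex to taxon label in ``{1..n}``.
        Defaults to the identity on the leaf vertices (which must then be
        exactly ``1..n``-labelled for a structurally valid network).
    child_order:
        Optional explicit visit order for the children of selected
        vertices.  Traversals expand children in increasing vertex id
        unless an explicit order is given; the override exists so that a
        network can reproduce the child ordering in which it was drawn.
    """

    def __init__(
        self,
        edges: Iterable[tuple[int, int]],
        *,
        leaf_labels: Mapping[int, int] | None = None,
        child_order: Mapping[int, Sequence[int]] | None = None,
    ) -> None:
        edges = list(edges)
        seen: set[tuple[int, int]] = set()
        for e in edges:
            if e in seen:
                raise NetworkError(f"parallel edge {e!r} is not allowed")
            seen.add(e)
            if e[0] == e[1]:
                raise NetworkError(f"self-loop {e!r} is not allowed")
        g = nx.DiGraph()
        g.add_edges_from(edges)
        if g.number_of_nodes() == 0:
            raise NetworkError("a network needs at least one edge")
        roots = [v for v in g if g.in_degree(v) == 0]
        if len(roots) != 1:
            raise NetworkError(
                f"expected exactly one indegree-0 vertex, found {sorted(roots)}"
            )
        self._g = g
        self.root: int = roots[0]
        leaves = sorted(v for v in g if g.out_degree(v) == 0)
        if leaf_labels is None:
            leaf_labels = {v: v for v in leaves}
        else:
            leaf_labels = dict(leaf_labels)
            if sorted(leaf_labels) != leaves:
                raise NetworkError("leaf_labels domain must be exactly the leaves")
        self.leaf_labels: dict[int, int] = leaf_labels
        self.child_order: dict[int, tuple[int, ...]] = {}
        if child_order:
            for v, order in child_order.items():
                if sorted(order) != sorted(g.successors(v)):
                    raise NetworkError(
                        f"child_order for vertex {v} must permute its children"
                    )
                self.child_order[v] = tuple(order)

    # -- basic accessors -------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        return self._g

    @property
    def vertices(self) -> list[int]:
        return sorted(self._g.nodes)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(self._g.edges)

    @property
    def leaves(self) -> list[int]:
        return sorted(v for v in self._g if self._g.out_degree(v) == 0)

    @property
    def n(self) -> int:
        """Number of leaves."""
        return len(self.leaf_labels)

    @property
    def reticulations(self) -> list[int]:
        return sorted(v for v in self._g if self._g.in_degree(v) >= 2)

    @property
    def r(self) -> int:
        """Number of reticulate vertices."""
        return len(self.reticulations)

    def children(self, v: int) -> list[int]:
        """Children of ``v`` in traversal order (ascending unless overridden)."""
        if v in self.child_order:
            return list(self.child_order[v])
        return sorted(self._g.successors(v))

    def parents(self, v: int) -> list[int]:
        return sorted(self._g.predecessors(v))

    def in_degree(self, v: int) -> int:
        return self._g.in_degree(v)

    def out_degree(self, v: int) -> int:
        return self._g.out_degree(v)

    def has_vertex(self, v: int) -> bool:
        return v in self._g

    def is_reticulate(self, v: int) -> bool:
        return self._g.in_degree(v) >= 2

    def is_tree_edge(self, e: tuple[int, int]) -> bool:
        """True iff the head of ``e`` is not reticulate."""
        return not self.is_reticulate(e[1])

    def label_of(self, leaf: int) -> int:
        return self.leaf_labels[leaf]

    def leaf_for_label(self, label: int) -> int:
        for v, lab in self.leaf_labels.items():
            if lab == label:
                return v
        raise NetworkError(f"no leaf with label {label}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloNetwork):
            return NotImplemented
        return (
            self.edges == other.edges
            and self.leaf_labels == other.leaf_labels
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"PhyloNetwork(n={self.n}, r={self.r}, "
            f"|V|={self._g.number_of_nodes()}, root={self.root})"
        )


@dataclass
class ValidationReport:
    """Violations found by validation, grouped into tiers.

    Tiers: ``dag`` (acyclic, single root, all vertices reachable from it),
    ``degrees`` (signature membership, leaf-label bijection, the
    ``|V| = 2(n+r)-1`` identity), ``edge_condition`` (every edge has a
    tree-vertex endpoint) and ``time_consistency``.
    """

    violations: list[tuple[str, object, str]] = field(default_factory=list)
    tiers_checked: set[str] = field(default_factory=set)

    _TIER_OF_RULE = {
        "acyclic": "dag",
        "single_root": "dag",
        "reachable": "dag",
        "degree_combination": "degrees",
        "leaf_label_bijection": "degrees",
        "vertex_count": "degrees",
        "tree_endpoint": "edge_condition",
        "coexistence": "time_consistency",
    }

    def add(self, rule: str, subject: object, message: str) -> None:
        self.violations.append((rule, subject, message))

    def is_valid(self, tier: str | None = None) -> bool:
        if tier is None:
            return not self.violations
        return not any(
            self._TIER_OF_RULE.get(rule) == tier for rule, _, _ in self.violations
        )

    def merged_with(self, other: "ValidationReport") -> "ValidationReport":
        out = ValidationReport(
            violations=self.violations + other.violations,
            tiers_checked=self.tiers_checked | other.tiers_checked,
        )
        return out


def classify_vertex(net: PhyloNetwork, v: int) -> Role:
    """Classify ``v`` by its (indegree, outdegree) signature."""
    if not net.has_vertex(v):
        raise NetworkError(f"unknown vertex {v}")
    sig = (net.in_degree(v), net.out_degree(v))
    if sig == (0, 2):
        return Role.ROOT
    if sig == (1, 0):
        return Role.LEAF
    if sig == (1, 2):
        return Role.INTERNAL_TREE
    if sig == (2, 1):
        return Role.RETICULATE
    raise NetworkError(
        f"vertex {v} has degree signature {sig}, outside the four allowed"
    )


def validate_structure(net: PhyloNetwork) -> ValidationReport:
    """Check the structural tiers (dag, degrees, edge condition).

    Violations are recorded, not raised; time-consistency is checked
    separately by :func:`validate_time_consistency`.
    """
    rep = ValidationReport(tiers_checked={"dag", "degrees", "edge_condition"})
    g = net.graph
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        rep.add("acyclic", tuple(cycle), "graph contains a directed cycle")
    roots = [v for v in g if g.in_degree(v) == 0]
    if len(roots) != 1:
        rep.add("single_root", tuple(roots), "not exactly one indegree-0 vertex")
    if rep.is_valid("dag"):
        reachable = nx.descendants(g, net.root) | {net.root}
        for v in g:
            if v not in reachable:
                rep.add("reachable", v, "vertex not reachable from the root")

    for v in g:
        sig = (g.in_degree(v), g.out_degree(v))
        if sig not in ALLOWED_DEGREES:
            rep.add(
                "degree_combination",
                v,
                f"degree signature {sig} not in {sorted(ALLOWED_DEGREES)}",
            )
    labels = sorted(net.leaf_labels.values())
    if labels != list(range(1, len(labels) + 1)):
        rep.add(
            "leaf_label_bijection",
            tuple(labels),
            "leaf labels are not exactly {1..n}",
        )
    expected = 2 * (net.n + net.r) - 1
    if g.number_of_nodes() != expected:
        rep.add(
            "vertex_count",
            g.number_of_nodes(),
            f"|V| = {g.number_of_nodes()} but 2(n+r)-1 = {expected}",
        )
    for u, v in g.edges:
        if net.is_reticulate(u) and net.is_reticulate(v):
            rep.add("tree_endpoint", (u, v), "edge has no tree-vertex endpoint")
    return rep


def _tree_edge_reach(net: PhyloNetwork) -> np.ndarray:
    """Boolean matrix R with R[u, v] = a directed path from u to v exists
    that contains at least one tree edge."""
    verts = net.vertices
    idx = {v: i for i, v in enumerate(verts)}
    m = len(verts)
    g = net.graph
    closure = np.zeros((m, m), dtype=bool)
    for v in verts:
        for d in nx.descendants(g, v):
            closure[idx[v], idx[d]] = True
    reach_eq = closure | np.eye(m, dtype=bool)  # reaches via a possibly empty path
    out = np.zeros((m, m), dtype=bool)
    for u, v in g.edges:
        if net.is_tree_edge((u, v)):
            # any path u' => u -> v => v' passing through this tree edge
            out |= np.outer(reach_eq[:, idx[u]], reach_eq[idx[v], :])
    return out


def cannot_coexist(net: PhyloNetwork, u: int, v: int) -> bool:
    """Decide the "cannot coexist in time" relation between ``u`` and ``v``.

    True iff there is a sequence of directed paths ``p_1 .. p_k``, each
    containing at least one tree edge, with ``u`` the tail of ``p_1``,
    ``v`` the head of ``p_k``, and the head of each ``p_i`` and the tail of
    ``p_{i+1}`` co-parents of some reticulate vertex.  Computed as the
    boolean fixed point ``S · (L · S)*`` where ``S`` is the
    tree-edge-path relation and ``L`` links co-parents of reticulations.
    Paths require at least one edge.
    """
    for x in (u, v):
        if not net.has_vertex(x):
            raise NetworkError(f"unknown vertex {x}")
    verts = net.vertices
    idx = {w: i for i, w in enumerate(verts)}
    seg = _tree_edge_reach(net)
    m = len(verts)
    link = np.zeros((m, m), dtype=bool)
    for w in net.reticulations:
        ps = net.parents(w)
        for a in ps:
            for b in ps:
                if a != b:
                    link[idx[a], idx[b]] = True
    def bmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return (a.astype(np.uint8) @ b.astype(np.uint8)) > 0

    acc = seg.copy()
    while True:
        nxt = acc | bmul(seg, bmul(link, acc))
        if (nxt == acc).all():
            break
        acc = nxt
    return bool(acc[idx[u], idx[v]])


def validate_time_consistency(net: PhyloNetwork) -> ValidationReport:
    """Flag every reticulate vertex whose parents cannot coexist in time."""
    rep = ValidationReport(tiers_checked={"time_consistency"})
    for w in net.reticulations:
        ps = net.parents(w)
        for a, b in ((ps[0], ps[1]), (ps[1], ps[0])):
            if cannot_coexist(net, a, b):
                rep.add(
                    "coexistence",
                    w,
                    f"parents {a} and {b} of reticulation {w} cannot coexist in time",
                )
                break
    return rep


def has_sister_reticulations(net: PhyloNetwork) -> bool:
    """True iff some vertex has two reticulate children.

    Networks with sister reticulations admit no displayed-tree semantics:
    removing one incoming edge per reticulation need not preserve the leaf
    set.
    """
    for v in net.vertices:
        kids = [w for w in net.graph.successors(v) if net.is_reticulate(w)]
        if len(kids) >= 2:
            return True
    return False
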