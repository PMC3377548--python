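"""Displayed trees of a network and the tree-based P1 criterion.

A network with ``r`` reticulate vertices and no *sister reticulations* (no
vertex with two reticulate children) displays exactly ``2^r`` phylogenetic
trees on the same leaf set: pick one incoming edge per reticulate vertex,
delete the others, and suppress the resulting degree-two vertices.  The
older P1 parsimony criterion scores a network as the minimum classic tree
parsimony score over these displayed trees; it is provided here both for
comparison with the all-edges P2 criterion and as the engine of the
displayed-tree Fitch bounds.

Suppression is iterated to a fixed point: deleting a reticulation edge can
cascade (the tree vertex that lost a child drops to outdegree one, and so
may its parent after contraction).  If the root drops to outdegree one its
edge is contracted and the child becomes the new root.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import networkx as nx

from .network import NetworkError, PhyloNetwork, has_sister_reticulations
from .sankoff import CostMatrix
from .traversal import post_order

__all__ = [
    "DisplayedTree",
    "display_tree",
    "enumerate_displayed_trees",
    "score_p1_exhaustive",
    "sankoff_tree",
    "fitch_tree",
    "to_newick",
]

MAX_ENUMERABLE_R = 12


@dataclass
class DisplayedTree:
    """One tree displayed by a network."""

    tree: PhyloNetwork
    choice: dict[int, tuple[int, int]]  # reticulation -> retained in-edge
    contraction_log: list[tuple[int, tuple[int, int]]]  # (removed vertex, merged edge)


def _suppress(g: nx.DiGraph, root: int) -> tuple[nx.DiGraph, int, list]:
    """Iteratively remove indegree-1/outdegree-1 vertices (merging their
    edges) and contract a root edge whenever the root drops to outdegree 1."""
    log: list[tuple[int, tuple[int, int]]] = []
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if v == root and g.out_degree(v) == 1:
                (child,) = g.successors(v)
                g.remove_node(v)
                log.append((v, (v, child)))
                root = child
                changed = True
                break
            if v != root and g.in_degree(v) == 1 and g.out_degree(v) == 1:
                (u,) = g.predecessors(v)
                (w,) = g.successors(v)
                if g.has_edge(u, w):  # would create a parallel edge
                    raise NetworkError(
                        f"suppressing vertex {v} would duplicate edge ({u}, {w})"
                    )
                g.remove_node(v)
                g.add_edge(u, w)
                log.append((v, (u, w)))
                changed = True
                break
    return g, root, log


def display_tree(
    net: PhyloNetwork, choice: Mapping[int, tuple[int, int]]
) -> DisplayedTree:
    """Build the tree displayed by ``net`` under ``choice``, which selects
    the retained incoming edge of every reticulate vertex."""
    if has_sister_reticulations(net):
        raise NetworkError(
            "displayed trees are defined only for networks with no sister "
            "reticulations"
        )
    retic = net.reticulations
    if sorted(choice) != retic:
        raise NetworkError(
            f"choice must select one in-edge for each reticulation {retic}"
        )
    g = net.graph.copy()
    for w, (u, _w) in choice.items():
        if _w != w or not g.has_edge(u, w):
            raise NetworkError(f"choice for reticulation {w} is not an in-edge")
        for p in list(g.predecessors(w)):
            if p != u:
                g.remove_edge(p, w)
    g, _root, log = _suppress(g, net.root)
    tree = PhyloNetwork(g.edges, leaf_labels=net.leaf_labels)
    if tree.leaves != net.leaves:
        raise NetworkError("displayed tree lost leaves (malformed network)")
    return DisplayedTree(tree=tree, choice=dict(choice), contraction_log=log)


def enumerate_displayed_trees(net: PhyloNetwork) -> list[DisplayedTree]:
    """All ``2^r`` displayed trees, enumerated as a binary counter over the
    reticulations in post-order, in-edges of each sorted by parent id."""
    if has_sister_reticulations(net):
        raise NetworkError(
            "displayed trees are defined only for networks with no sister "
            "reticulations"
        )
    post = post_order(net)
    retic = sorted(net.reticulations, key=lambda w: post.position[w])
    per_vertex = [[(p, w) for p in net.parents(w)] for w in retic]
    out = []
    for combo in itertools.product(*per_vertex):
        out.append(display_tree(net, dict(zip(retic, combo))))
    return out


# ---------------------------------------------------------------------------
# classic algorithms on trees (the r = 0 specialization oracle and the
# engine behind P1)
# ---------------------------------------------------------------------------


def _require_tree(net: PhyloNetwork) -> None:
    if net.r != 0:
        raise NetworkError("input has reticulations; use the network routines")


def sankoff_tree(
    tree: PhyloNetwork, site: Mapping[int, int | None], cost: CostMatrix
) -> tuple[float, dict[int, int]]:
    """Classic weighted parsimony on a tree: score and one optimal
    extension (smallest state index on ties)."""
    _require_tree(tree)
    k = cost.k
    post = post_order(tree)
    S: dict[int, list[float]] = {}
    for v in post.order:
        if tree.out_degree(v) == 0:
            st = site[tree.label_of(v)]
            S[v] = [0.0 if (st is None or i == st) else float("inf") for i in range(k)]
        else:
            S[v] = [
                sum(
                    min(cost.costs[i, j] + S[w][j] for j in range(k))
                    for w in tree.children(v)
                )
                for i in range(k)
            ]
    root = tree.root
    score = min(S[root])
    ext = {root: S[root].index(score)}
    for v in pre_order_iter(tree):
        for w in tree.children(v):
            i = ext[v]
            best = min(range(k), key=lambda j: (cost.costs[i, j] + S[w][j], j))
            ext[w] = best
    return float(score), ext


def fitch_tree(
    tree: PhyloNetwork, site: Mapping[int, int | None]
) -> tuple[int, dict[int, int]]:
    """Classic Fitch change counting on a (binary) tree: the minimum number
    of state changes and one optimal extension."""
    _require_tree(tree)
    post = post_order(tree)
    A: dict[int, frozenset[int]] = {}
    count = 0
    for v in post.order:
        if tree.out_degree(v) == 0:
            st = site[tree.label_of(v)]
            if st is None:
                raise NetworkError("Fitch requires fully observed leaves")
            A[v] = frozenset({st})
        else:
            kids = tree.children(v)
            acc = A[kids[0]]
            for w in kids[1:]:
                inter = acc & A[w]
                if inter:
                    acc = inter
                else:
                    acc = acc | A[w]
                    count += 1
            A[v] = acc
    ext = {tree.root: min(A[tree.root])}
    for v in pre_order_iter(tree):
        for w in tree.children(v):
            ext[w] = ext[v] if ext[v] in A[w] else min(A[w])
    return count, ext


def pre_order_iter(net: PhyloNetwork):
    """Vertices of a tree in pre-order (helper for the classic routines)."""
    stack = [net.root]
    while stack:
        v = stack.pop()
        yield v
        for w in reversed(net.children(v)):
            stack.append(w)


def score_p1_exhaustive(
    net: PhyloNetwork, site: Mapping[int, int | None], cost: CostMatrix
) -> tuple[float, int, dict[int, int]]:
    """The P1 criterion: minimum classic tree parsimony score over all
    displayed trees.  Returns ``(score, index of the best displayed tree,
    extension on that tree)``."""
    if net.r > MAX_ENUMERABLE_R:
        raise NetworkError(
            f"r = {net.r} exceeds the enumeration guard ({MAX_ENUMERABLE_R})"
        )
    best: tuple[float, int, dict[int, int]] | None = None
    for i, dt in enumerate(enumerate_displayed_trees(net)):
        score, ext = sankoff_tree(dt.tree, site, cost)
        if best is None or score < best[0]:
            best = (score, i, ext)
    assert best is not None
    return best


def to_newick(tree: PhyloNetwork, *, internal_labels: bool = False) -> str:
    """Serialize a tree (r = 0) as plain Newick."""
    _require_tree(tree)

    def render(v: int) -> str:
        kids = tree.children(v)
        if not kids:
            return str(tree.label_of(v))
        inner = ",".join(render(w) for w in kids)
        return f"({inner}){v if internal_labels else ''}"

    return render(tree.root) + ";"
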