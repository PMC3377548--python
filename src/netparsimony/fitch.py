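"""Change counting on networks (network Fitch).

Under the unit cost matrix (zero diagonal, one off-diagonal) the parsimony
score counts state changes along edges.  Fitch's set-based algorithm
extends to networks: the post-order sweep builds a state set ``A(v)`` per
vertex (intersection where possible, union at a cost of one change), with
a reticulate vertex — outdegree one — simply copying its child's set; the
pre-order sweep assigns concrete states down the traversal tree, keeping
the parent's state whenever it is available.

The counter ``UB`` maintained by the sweeps is a heuristic: the paper's
fixing step adjusts it only when the non-traversal parent's state lies in
``A(v)`` yet differs from the assigned state, so it can disagree with the
true edge count of the returned extension.  The module therefore always
reports ``direct_score`` — the unit-cost edge-sum of the concrete
extension — which is provably a valid upper bound on the optimum, and
treats it as authoritative.

For networks with no sister reticulations, a classic Fitch run on any
displayed tree is a lower bound on the network optimum, and extending that
tree's assignment to the whole network gives an upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .displayed import DisplayedTree, display_tree, fitch_tree
from .network import NetworkError, PhyloNetwork
from .sankoff import CostMatrix, evaluate_p2
from .traversal import post_order, pre_order

__all__ = [
    "FitchResult",
    "fitch_post_order",
    "fitch_pre_order",
    "fitch_network",
    "fitch_displayed_bounds",
]


@dataclass
class FitchResult:
    A: dict[int, frozenset[int]]
    ub: int
    extension: dict[int, int]
    direct_score: int


def fitch_post_order(
    net: PhyloNetwork, site: Mapping[int, int | None]
) -> tuple[dict[int, frozenset[int]], int]:
    """Post-order sweep: per-vertex state sets and the union-count ``UB``.

    Reticulate vertices (single child) copy the child's set without
    incrementing the counter.
    """
    post = post_order(net)
    A: dict[int, frozenset[int]] = {}
    ub = 0
    for v in post.order:
        if net.out_degree(v) == 0:
            st = site[net.label_of(v)]
            if st is None:
                raise NetworkError(
                    f"leaf {net.label_of(v)} is unassigned; Fitch requires "
                    "fully observed leaves"
                )
            A[v] = frozenset({st})
        else:
            kids = net.children(v)
            if len(kids) == 1:
                A[v] = A[kids[0]]
            else:
                inter = A[kids[0]] & A[kids[1]]
                if inter:
                    A[v] = inter
                else:
                    A[v] = A[kids[0]] | A[kids[1]]
                    ub += 1
    return A, ub


def fitch_pre_order(
    net: PhyloNetwork, fr: tuple[dict[int, frozenset[int]], int]
) -> FitchResult:
    """Pre-order sweep: assign states down the traversal tree and fix the
    counter at the reticulations.

    The root takes the smallest state in ``A(root)``; every other vertex
    keeps its traversal-tree parent's state when that state lies in its own
    set, otherwise the smallest member of the set.  At each reticulate
    vertex, if the other parent's state lies in the set but differs from
    the assigned state, ``UB`` is incremented.
    """
    A, ub = fr
    pre = pre_order(net)
    parent_in_tree = {b: a for (a, b) in pre.traversal_tree_edges}
    ext: dict[int, int] = {}
    for v in pre.order:
        if v == net.root:
            ext[v] = min(A[v])
        else:
            u = parent_in_tree[v]
            ext[v] = ext[u] if ext[u] in A[v] else min(A[v])
    for w in net.reticulations:
        u_tree = parent_in_tree[w]
        for u2 in net.parents(w):
            if u2 != u_tree and ext[u2] in A[w] and ext[u2] != ext[w]:
                ub += 1
    unit = CostMatrix.unit(max(max(s) for s in A.values()) + 1)
    direct = int(evaluate_p2(net, ext, unit))
    return FitchResult(A=A, ub=ub, extension=ext, direct_score=direct)


def fitch_network(
    net: PhyloNetwork, site: Mapping[int, int | None]
) -> FitchResult:
    """Both sweeps on one site."""
    return fitch_pre_order(net, fitch_post_order(net, site))


def fitch_displayed_bounds(
    net: PhyloNetwork, site: Mapping[int, int | None]
) -> tuple[int, int, DisplayedTree]:
    """Displayed-tree bounds for no-sister networks under unit costs.

    The default displayed tree retains, for each reticulation, the edge
    from its traversal-tree parent.  A classic Fitch count on that tree is
    a lower bound on the network optimum; lifting the tree's assignment
    back onto the whole network (suppressed vertices copy the state of the
    surviving vertex reached by walking down their retained-edge chain) and
    pricing all network edges gives an upper bound.
    """
    pre = pre_order(net)
    parent_in_tree = {b: a for (a, b) in pre.traversal_tree_edges}
    choice = {w: (parent_in_tree[w], w) for w in net.reticulations}
    dt = display_tree(net, choice)
    lower, tree_ext = fitch_tree(dt.tree, site)

    # graph before suppression: the network minus the non-retained edges
    kept = {e for e in net.edges if not net.is_reticulate(e[1])}
    kept |= set(choice.values())
    children_kept: dict[int, list[int]] = {}
    for (u, v) in kept:
        children_kept.setdefault(u, []).append(v)

    ext = dict(tree_ext)

    def lift(v: int) -> int:
        if v in ext:
            return ext[v]
        kids = children_kept.get(v, [])
        if len(kids) != 1:  # a suppressed vertex has exactly one kept child
            raise AssertionError(f"vertex {v} unexpectedly unassigned")
        ext[v] = lift(kids[0])
        return ext[v]

    for v in net.vertices:
        lift(v)
    k = max(max(ext.values()), max(st for st in site.values() if st is not None)) + 1
    upper = int(evaluate_p2(net, ext, CostMatrix.unit(k)))
    return lower, upper, dt
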