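"""Depth-first traversals of a phylogenetic network from its root.

Because a reticulate vertex has two parents, a depth-first walk of the
network visits it only the first time it is reached; both the pre-order and
the post-order walk therefore trace the same spanning tree of the network,
the *traversal tree*.  Children are expanded in increasing order of their
integer labels (unless the network carries an explicit child order), which
fixes the orders uniquely and guarantees order-consistency: for two
vertices with no directed path between them, their relative order is the
same in pre-order and post-order.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import NetworkError, PhyloNetwork

__all__ = [
    "TraversalResult",
    "pre_order",
    "post_order",
    "satisfies_traversal_condition",
    "traversal_condition_parent",
]


@dataclass(frozen=True)
class TraversalResult:
    """A vertex order, its rank map, and the traversal-tree edges."""

    order: tuple[int, ...]
    position: dict[int, int]
    traversal_tree_edges: frozenset[tuple[int, int]]

    def precedes(self, u: int, v: int) -> bool:
        return self.position[u] < self.position[v]

    def tree_parent(self, v: int) -> int | None:
        """Traversal-tree parent of ``v`` (None for the root)."""
        for (a, b) in self.traversal_tree_edges:
            if b == v:
                return a
        return None


def _dfs(net: PhyloNetwork) -> tuple[list[int], list[int], set[tuple[int, int]]]:
    """One iterative depth-first walk, yielding pre- and post-orders and the
    traversal tree.  Raises on cycles (a vertex re-entered while open)."""
    pre: list[int] = []
    post: list[int] = []
    tree_edges: set[tuple[int, int]] = set()
    visited: set[int] = set()
    open_set: set[int] = set()
    root = net.root
    # stack of (vertex, iterator over its ordered children)
    stack: list[tuple[int, list[int], int]] = []

    visited.add(root)
    open_set.add(root)
    pre.append(root)
    stack.append((root, net.children(root), 0))
    while stack:
        v, kids, i = stack.pop()
        while i < len(kids) and kids[i] in visited:
            if kids[i] in open_set:
                raise NetworkError(f"cycle detected through vertex {kids[i]}")
            i += 1
        if i == len(kids):
            post.append(v)
            open_set.discard(v)
            continue
        w = kids[i]
        stack.append((v, kids, i + 1))
        visited.add(w)
        open_set.add(w)
        pre.append(w)
        tree_edges.add((v, w))
        stack.append((w, net.children(w), 0))
    return pre, post, tree_edges


def pre_order(net: PhyloNetwork) -> TraversalResult:
    """Depth-first pre-order from the root; each vertex visited once."""
    pre, _, tree = _dfs(net)
    return TraversalResult(
        order=tuple(pre),
        position={v: i for i, v in enumerate(pre)},
        traversal_tree_edges=frozenset(tree),
    )


def post_order(net: PhyloNetwork) -> TraversalResult:
    """Depth-first post-order from the root; each vertex visited once."""
    _, post, tree = _dfs(net)
    return TraversalResult(
        order=tuple(post),
        position={v: i for i, v in enumerate(post)},
        traversal_tree_edges=frozenset(tree),
    )


def satisfies_traversal_condition(
    net: PhyloNetwork, v: int, w: int, post: TraversalResult
) -> bool:
    """Decide whether child ``w`` satisfies the traversal condition w.r.t.
    parent ``v``: ``w`` is reticulate and ``v`` precedes the other parent of
    ``w`` in post-order.  For a non-reticulate ``w`` the condition is false
    by definition."""
    if (v, w) not in net.graph.edges:
        raise NetworkError(f"({v}, {w}) is not an edge")
    if not net.is_reticulate(w):
        return False
    others = [p for p in net.parents(w) if p != v]
    return all(post.precedes(v, p) for p in others)


def traversal_condition_parent(
    net: PhyloNetwork, w: int, post: TraversalResult
) -> int:
    """The unique parent of reticulate ``w`` satisfying the traversal
    condition (the parent earliest in post-order)."""
    if not net.is_reticulate(w):
        raise NetworkError(f"vertex {w} is not reticulate")
    return min(net.parents(w), key=lambda p: post.position[p])
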