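"""Weighted parsimony on phylogenetic networks (network Sankoff).

The parsimony score of a fully assigned network is the sum of substitution
costs ``c_ij`` over *all* edges of the network, where ``i`` and ``j`` are
the states at the tail and head of each edge.  Minimizing this score over
all extensions of the observed leaf states is solved exactly on trees by
Sankoff's dynamic programme; on networks the same post-order recursion
yields a *lower bound* ``S`` (a reticulate vertex may be priced with two
different states by its two parents), and the pre-order backtrack yields a
concrete conflict-free extension whose score ``S'`` is an *upper bound*.

The post-order recursion prices the edge ``(v, w)`` as

* ``min_j [c_ij + S_w(j)]`` when ``w`` is not reticulate, or when ``w`` is
  reticulate and ``v`` is the parent earlier in post-order (``w``
  *satisfies the traversal condition* with respect to ``v``) — that parent
  accounts for the whole subnetwork below ``w``;
* ``min_j c_ij`` when ``v`` is the other parent of a reticulate ``w`` —
  only the cheapest substitution along the edge itself, since the state
  eventually assigned at ``w`` is unknown at this point.

A *conflict* arises when the two parents of a reticulate vertex backtrack
different preferred states; the state preferred by the traversal-condition
parent wins and the upper bound is corrected by ``- c_{i'j'} + c_{i'j}``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import NetworkError, PhyloNetwork
from .traversal import (
    TraversalResult,
    post_order,
    satisfies_traversal_condition,
    traversal_condition_parent,
)

__all__ = [
    "CostMatrix",
    "LeafAssignment",
    "SankoffTables",
    "Conflict",
    "BoundsResult",
    "sankoff_post_order",
    "sankoff_pre_order",
    "sankoff_bounds",
    "evaluate_p2",
    "majority_upper_bound",
]

INF = math.inf


@dataclass(frozen=True)
class CostMatrix:
    """A k-by-k nonnegative substitution cost matrix over an ordered alphabet.

    ``costs[i, j]`` is the cost of transforming state ``i`` into state
    ``j`` along any edge of the network.
    """

    alphabet: tuple[str, ...]
    costs: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.costs, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("cost matrix must be square")
        if c.shape[0] != len(self.alphabet):
            raise ValueError("cost matrix size must match the alphabet")
        if (c < 0).any():
            raise ValueError("substitution costs must be nonnegative")
        object.__setattr__(self, "costs", c)

    @property
    def k(self) -> int:
        return len(self.alphabet)

    def index(self, symbol: str) -> int:
        try:
            return self.alphabet.index(symbol)
        except ValueError:
            raise ValueError(
                f"symbol {symbol!r} not in alphabet {self.alphabet}"
            ) from None

    @classmethod
    def unit(cls, k: int = 2, alphabet: Sequence[str] | None = None) -> "CostMatrix":
        """The change-counting matrix: zero diagonal, one off-diagonal."""
        if alphabet is None:
            alphabet = tuple(str(i) for i in range(k))
        k = len(alphabet)
        return cls(tuple(alphabet), np.ones((k, k)) - np.eye(k))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CostMatrix):
            return NotImplemented
        return self.alphabet == other.alphabet and np.array_equal(
            self.costs, other.costs
        )


@dataclass(frozen=True)
class LeafAssignment:
    """Observed states at the leaves, one per leaf label per site.

    ``data[label]`` is a tuple of state indices (``None`` marks missing
    data) of length ``sites``.
    """

    data: Mapping[int, tuple[int | None, ...]]
    sites: int

    def __post_init__(self) -> None:
        for label, states in self.data.items():
            if len(states) != self.sites:
                raise ValueError(
                    f"leaf {label} has {len(states)} states, expected {self.sites}"
                )

    def site(self, s: int = 0) -> dict[int, int | None]:
        """The single-site map ``leaf label -> state index``."""
        return {label: states[s] for label, states in self.data.items()}

    @classmethod
    def single_site(cls, site: Mapping[int, int | None]) -> "LeafAssignment":
        return cls({lab: (st,) for lab, st in site.items()}, sites=1)

    @classmethod
    def from_symbols(
        cls, rows: Mapping[int, Sequence[str]], alphabet: Sequence[str]
    ) -> "LeafAssignment":
        """Resolve symbol rows against an alphabet; ``'?'`` marks missing."""
        alpha = list(alphabet)
        data = {}
        sites = None
        for label, symbols in rows.items():
            states = []
            for sym in symbols:
                if sym == "?":
                    states.append(None)
                elif sym in alpha:
                    states.append(alpha.index(sym))
                else:
                    raise ValueError(
                        f"symbol {sym!r} at leaf {label} not in alphabet {alpha}"
                    )
            if sites is None:
                sites = len(states)
            elif sites != len(states):
                raise ValueError("ragged character matrix")
            data[label] = tuple(states)
        return cls(data, sites=sites or 0)


@dataclass
class SankoffTables:
    """Per-vertex state costs and per-edge backtracking tables.

    ``S[v][i]`` is a lower bound on the total substitution cost of the
    subnetwork reachable from ``v`` given state ``i`` at ``v``;
    ``s[(v, w)][i]`` and ``t[(v, w)][i]`` are the cost contribution of edge
    ``(v, w)`` and the child state achieving it.
    """

    S: dict[int, np.ndarray]
    s: dict[tuple[int, int], np.ndarray]
    t: dict[tuple[int, int], np.ndarray]
    post: TraversalResult
    pinned: dict[int, int] = field(default_factory=dict)


@dataclass(frozen=True)
class Conflict:
    """A reticulate vertex whose parents backtracked different states."""

    vertex: int
    parents: tuple[int, int]  # (traversal-condition parent, other parent)
    states: tuple[int, int]  # (j preferred by tc parent, j' by the other)
    assigned: int


@dataclass
class BoundsResult:
    lower: float
    upper: float
    extension: dict[int, int]
    conflicts: list[Conflict]


def _leaf_costs(k: int, state: int | None) -> np.ndarray:
    if state is None:  # missing data: any state free of charge
        return np.zeros(k)
    col = np.full(k, INF)
    if not 0 <= state < k:
        raise NetworkError(f"leaf state {state} outside alphabet of size {k}")
    col[state] = 0.0
    return col


def _edge_cost(
    cost: CostMatrix, edge: tuple[int, int], edge_weights: Mapping | None
) -> np.ndarray:
    if edge_weights is None:
        return cost.costs
    w = edge_weights.get(edge, 1.0)
    if w < 0:
        raise ValueError(f"edge weight for {edge} must be nonnegative")
    return w * cost.costs


def sankoff_post_order(
    net: PhyloNetwork,
    site: Mapping[int, int | None],
    cost: CostMatrix,
    *,
    pinned: Mapping[int, int] | None = None,
    edge_weights: Mapping[tuple[int, int], float] | None = None,
) -> SankoffTables:
    """Post-order phase: fill the cost tables bottom-up.

    ``site`` maps leaf labels to state indices (``None`` = missing).
    ``pinned`` optionally restricts chosen vertices (in practice the
    reticulations) to a single state, which is how the exact enumeration
    and the majority heuristic reuse this routine unchanged.
    """
    k = cost.k
    pinned = dict(pinned or {})
    post = post_order(net)
    S: dict[int, np.ndarray] = {}
    s: dict[tuple[int, int], np.ndarray] = {}
    t: dict[tuple[int, int], np.ndarray] = {}
    for v in post.order:
        if net.out_degree(v) == 0:
            label = net.label_of(v)
            if label not in site:
                raise NetworkError(f"leaf {label} has no assigned state")
            S[v] = _leaf_costs(k, site[label])
        else:
            total = np.zeros(k)
            for w in net.children(v):
                C = _edge_cost(cost, (v, w), edge_weights)
                allowed = np.zeros(k) if w not in pinned else np.full(k, INF)
                if w in pinned:
                    allowed[pinned[w]] = 0.0
                if (not net.is_reticulate(w)) or satisfies_traversal_condition(
                    net, v, w, post
                ):
                    m = C + S[w][None, :] + allowed[None, :]
                else:
                    m = C + allowed[None, :]
                s[(v, w)] = m.min(axis=1)
                t[(v, w)] = m.argmin(axis=1)  # ties -> smallest state index
                total = total + s[(v, w)]
            S[v] = total
        if v in pinned:
            mask = np.full(k, INF)
            mask[pinned[v]] = 0.0
            S[v] = S[v] + mask
    return SankoffTables(S=S, s=s, t=t, post=post, pinned=pinned)


def _accounting_parent(net: PhyloNetwork, w: int, post: TraversalResult) -> int:
    """The parent through which the DP accounts the subnetwork below ``w``:
    the traversal-condition parent for a reticulate vertex, the unique
    parent otherwise.  On time-consistent networks this is exactly the
    traversal-tree parent."""
    if net.is_reticulate(w):
        return traversal_condition_parent(net, w, post)
    return net.parents(w)[0]


def sankoff_pre_order(
    net: PhyloNetwork,
    tables: SankoffTables,
    cost: CostMatrix,
    *,
    edge_weights: Mapping[tuple[int, int], float] | None = None,
) -> BoundsResult:
    """Pre-order phase: backtrack an extension and fix reticulate conflicts.

    Returns the lower bound ``S = min_i S_root(i)``, the backtracked
    conflict-free extension, the conflict records, and the upper bound
    ``S'`` obtained from ``S`` by replacing, at every reticulate vertex,
    the optimistic price of the non-accounting edge with the price of the
    state actually assigned.  ``S'`` always equals the parsimony score
    (:func:`evaluate_p2`) of the returned extension.
    """
    post = tables.post
    S_root = tables.S[net.root]
    lower = float(S_root.min())
    ext: dict[int, int] = {net.root: int(S_root.argmin())}
    # assign every vertex from its accounting parent, parents first
    children_of: dict[int, list[int]] = {v: [] for v in net.vertices}
    for w in net.vertices:
        if w != net.root:
            children_of[_accounting_parent(net, w, post)].append(w)
    stack = [net.root]
    while stack:
        v = stack.pop()
        for w in sorted(children_of[v], reverse=True):
            ext[w] = int(tables.t[(v, w)][ext[v]])
            stack.append(w)

    upper = lower
    conflicts: list[Conflict] = []
    for w in net.reticulations:
        v = traversal_condition_parent(net, w, post)
        (v2,) = [p for p in net.parents(w) if p != v]
        i2 = ext[v2]
        j = ext[w]  # state preferred by the traversal-condition parent
        j2 = int(tables.t[(v2, w)][i2])
        C2 = _edge_cost(cost, (v2, w), edge_weights)
        upper = upper - float(C2[i2, j2]) + float(C2[i2, j])
        if j != j2:
            conflicts.append(
                Conflict(vertex=w, parents=(v, v2), states=(j, j2), assigned=j)
            )
    return BoundsResult(lower=lower, upper=upper, extension=ext, conflicts=conflicts)


def sankoff_bounds(
    net: PhyloNetwork,
    site: Mapping[int, int | None],
    cost: CostMatrix,
    *,
    pinned: Mapping[int, int] | None = None,
    edge_weights: Mapping[tuple[int, int], float] | None = None,
) -> BoundsResult:
    """Run both phases on one site."""
    tables = sankoff_post_order(
        net, site, cost, pinned=pinned, edge_weights=edge_weights
    )
    return sankoff_pre_order(net, tables, cost, edge_weights=edge_weights)


def evaluate_p2(
    net: PhyloNetwork,
    ext: Mapping[int, int],
    cost: CostMatrix,
    *,
    edge_weights: Mapping[tuple[int, int], float] | None = None,
) -> float:
    """The parsimony score of a full assignment: the substitution cost
    summed over every edge of the network."""
    total = 0.0
    for (u, v) in net.edges:
        if u not in ext or v not in ext:
            raise NetworkError(f"extension misses a state for edge ({u}, {v})")
        C = _edge_cost(cost, (u, v), edge_weights)
        total += float(C[ext[u], ext[v]])
    return total


def _reachable_leaf_majority(
    net: PhyloNetwork, v: int, site: Mapping[int, int | None], k: int
) -> int:
    """The state occurring most often at the leaves reachable from ``v``
    (smallest state index on ties; state 0 if every reachable leaf is
    missing)."""
    import networkx as nx

    reach = nx.descendants(net.graph, v) | {v}
    counts = np.zeros(k, dtype=int)
    for leaf in net.leaves:
        if leaf in reach:
            st = site[net.label_of(leaf)]
            if st is not None:
                counts[st] += 1
    return int(counts.argmax())


def majority_upper_bound(
    net: PhyloNetwork,
    site: Mapping[int, int | None],
    cost: CostMatrix,
    *,
    edge_weights: Mapping[tuple[int, int], float] | None = None,
) -> tuple[float, dict[int, int]]:
    """Alternate upper bound: pin each reticulate vertex to the state that
    occurs most often among the leaves reachable from it, then rerun the
    dynamic programme.  The result is the score of a concrete conflict-free
    extension, hence a valid upper bound on the optimum."""
    pins = {
        w: _reachable_leaf_majority(net, w, site, cost.k)
        for w in net.reticulations
    }
    res = sankoff_bounds(net, site, cost, pinned=pins, edge_weights=edge_weights)
    if res.conflicts:  # pinned DP cannot conflict
        raise AssertionError("pinned dynamic programme produced a conflict")
    return res.upper, res.extension
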