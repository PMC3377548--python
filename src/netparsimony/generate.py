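"""Synthesis of random phylogenetic networks, characters and cost matrices.

The generator grows a random rooted binary tree by repeated joining of
subtree roots, then adds each reticulation by subdividing two distinct
edges and connecting the two new vertices — the standard construction that
preserves the degree signatures.  Candidates violating structural
validity, acyclicity, or (when required) time-consistency or the no-sister
condition are rejected and redrawn.  Everything is deterministic under the
seed.

By default generated networks are required to be time-consistent, since
time-consistency is part of the definition of a phylogenetic network; the
no-sister condition is optional because sister reticulations are legal
(they only preclude displayed-tree semantics).  The default desk scale
mirrors the regime the heuristics are meant for: small numbers of leaves
(single digits) and at most a couple of reticulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import (
    PhyloNetwork,
    has_sister_reticulations,
    validate_structure,
    validate_time_consistency,
)
from .sankoff import CostMatrix, LeafAssignment

__all__ = [
    "GeneratorConfig",
    "random_network",
    "random_characters",
    "random_cost_matrix",
    "fixture",
    "FIXTURES",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one random instance."""

    n: int = 5
    r: int = 1
    k: int = 2
    sites: int = 1
    seed: int = 0
    require_time_consistency: bool = True
    require_no_sister: bool = False
    max_tries: int = 2000

    def __post_init__(self) -> None:
        if self.n < 2 or self.r < 0 or self.k < 2:
            raise ValueError("need n >= 2, r >= 0, k >= 2")


def _random_binary_tree(n: int, rng: np.random.Generator) -> nx.DiGraph:
    """Random rooted binary tree with leaves 1..n (internal ids temporary)."""
    g = nx.DiGraph()
    roots = list(range(1, n + 1))
    next_id = n + 1
    while len(roots) > 1:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        a, b = roots[i], roots[j]
        g.add_edge(next_id, a)
        g.add_edge(next_id, b)
        roots = [r for r in roots if r not in (a, b)] + [next_id]
        next_id += 1
    return g


def _add_reticulation(g: nx.DiGraph, next_id: int, rng: np.random.Generator) -> int:
    """Subdivide two distinct random edges and join the new vertices."""
    edges = sorted(g.edges)
    i, j = rng.choice(len(edges), size=2, replace=False)
    (u1, v1), (u2, v2) = edges[i], edges[j]
    a, b = next_id, next_id + 1
    g.remove_edge(u1, v1)
    g.remove_edge(u2, v2)
    g.add_edge(u1, a)
    g.add_edge(a, v1)
    g.add_edge(u2, b)
    g.add_edge(b, v2)
    g.add_edge(a, b)  # b becomes the reticulate vertex
    return next_id + 2


def _relabel(g: nx.DiGraph, n: int) -> nx.DiGraph:
    """Leaves keep 1..n; internal vertices renumbered n+1.. in topological
    order (the root therefore gets n+1)."""
    order = [v for v in nx.lexicographical_topological_sort(g) if v > n]
    mapping = {old: n + 1 + i for i, old in enumerate(order)}
    mapping.update({v: v for v in range(1, n + 1)})
    return nx.relabel_nodes(g, mapping)


def random_network(cfg: GeneratorConfig) -> PhyloNetwork:
    """Draw one valid random network according to ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.max_tries):
        g = _random_binary_tree(cfg.n, rng)
        next_id = max(g.nodes) + 1
        ok = True
        for _ in range(cfg.r):
            next_id = _add_reticulation(g, next_id, rng)
            if not nx.is_directed_acyclic_graph(g):
                ok = False
                break
        if not ok:
            continue
        g = _relabel(g, cfg.n)
        try:
            net = PhyloNetwork(g.edges)
        except Exception:
            continue
        if not validate_structure(net).is_valid():
            continue
        if cfg.require_no_sister and has_sister_reticulations(net):
            continue
        if cfg.require_time_consistency and not validate_time_consistency(
            net
        ).is_valid():
            continue
        return net
    raise RuntimeError(
        f"no valid network found in {cfg.max_tries} tries for {cfg}"
    )


def random_characters(
    net: PhyloNetwork, k: int, sites: int, seed: int
) -> LeafAssignment:
    """Uniform i.i.d. leaf states, one column per site."""
    rng = np.random.default_rng(seed)
    labels = sorted(net.leaf_labels.values())
    draws = rng.integers(0, k, size=(len(labels), sites))
    return LeafAssignment(
        {lab: tuple(int(s) for s in draws[i]) for i, lab in enumerate(labels)},
        sites=sites,
    )


def random_cost_matrix(k: int, seed: int, mode: str = "unit") -> CostMatrix:
    """A cost matrix in one of three regimes.

    ``unit``
        zero diagonal, one off-diagonal (the change-counting matrix).
    ``integer``
        zero diagonal, independent integers in ``[0, 5]`` off-diagonal.
    ``metric``
        a random integer metric: symmetric positive off-diagonal entries
        closed under shortest paths, so the triangle inequality holds.
    """
    alphabet = tuple(str(i) for i in range(k))
    if mode == "unit":
        return CostMatrix.unit(k, alphabet)
    rng = np.random.default_rng(seed)
    if mode == "integer":
        c = rng.integers(0, 6, size=(k, k)).astype(float)
        np.fill_diagonal(c, 0.0)
        return CostMatrix(alphabet, c)
    if mode == "metric":
        c = rng.integers(1, 7, size=(k, k)).astype(float)
        c = np.minimum(c, c.T)
        np.fill_diagonal(c, 0.0)
        for m in range(k):  # Floyd-Warshall closure
            c = np.minimum(c, c[:, m, None] + c[None, m, :])
        return CostMatrix(alphabet, c)
    raise ValueError(f"unknown cost-matrix mode {mode!r}")


def _fig1_left() -> PhyloNetwork:
    # Single reticulation (vertex 8, parents 6 and 7).  The explicit root
    # child order (5, 4) matches the order in which the network is drawn
    # and reproduces its published traversal sequences.
    return PhyloNetwork(
        [(0, 5), (0, 4), (5, 6), (5, 7), (6, 1), (6, 8), (7, 3), (7, 8), (8, 2)],
        child_order={0: (5, 4)},
    )


def _fig1_right() -> PhyloNetwork:
    # Two reticulations (9 and 10) that are sister children of vertex 7.
    return PhyloNetwork(
        [
            (0, 5), (0, 8), (5, 6), (5, 7), (6, 1), (6, 9), (7, 9), (7, 10),
            (9, 2), (10, 3), (8, 10), (8, 4),
        ]
    )


FIXTURES = {
    "CHERRY": lambda: PhyloNetwork([(0, 1), (0, 2)]),
    "FIG1L": _fig1_left,
    "FIG1R": _fig1_right,
}


def fixture(name: str) -> PhyloNetwork:
    """Named reference networks.

    ``CHERRY`` is the two-leaf tree; ``FIG1L`` and ``FIG1R`` are the
    one-reticulation and sister-reticulation example networks whose pre-
    and post-order traversals are pinned by tests.
    """
    try:
        build = FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}"
        ) from None
    return build()
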