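"""Exact P2 optimum and the exhaustive brute-force oracle.

The exact optimum is obtained by enumerating all ``k^r`` combinations of
states at the reticulate vertices: with every reticulation pinned to a
single state the dynamic programme is exact (the free vertices form a tree
and the extra reticulate edges price against known states), so the minimum
over pinnings is the network optimum.

:func:`brute_force_score` minimizes the edge-sum directly over *all*
extensions of the leaf assignment.  It exists as an independent oracle for
testing and makes no use of the dynamic programme.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .network import NetworkError, PhyloNetwork
from .sankoff import CostMatrix, evaluate_p2, sankoff_bounds

__all__ = ["OptimumResult", "exact_score", "brute_force_score"]

MAX_R = 12
MAX_BRUTE_COMBOS = 10**7


@dataclass
class OptimumResult:
    score: float
    extension: dict[int, int]
    pinned_states: dict[int, int]
    combos_evaluated: int


def exact_score(
    net: PhyloNetwork,
    site: Mapping[int, int | None],
    cost: CostMatrix,
    *,
    edge_weights: Mapping[tuple[int, int], float] | None = None,
    max_r: int = MAX_R,
) -> OptimumResult:
    """Minimum parsimony score over all extensions, by ``k^r`` pinned runs
    of the dynamic programme (ties broken toward the lexicographically
    smallest pinning)."""
    retic = net.reticulations
    if len(retic) > max_r:
        raise NetworkError(f"r = {len(retic)} exceeds the guard ({max_r})")
    best: OptimumResult | None = None
    combos = 0
    for states in itertools.product(range(cost.k), repeat=len(retic)):
        pins = dict(zip(retic, states))
        res = sankoff_bounds(
            net, site, cost, pinned=pins, edge_weights=edge_weights
        )
        if res.conflicts:  # cannot happen with every reticulation pinned
            raise AssertionError("pinned dynamic programme produced a conflict")
        combos += 1
        if best is None or res.lower < best.score:
            best = OptimumResult(
                score=res.lower,
                extension=res.extension,
                pinned_states=pins,
                combos_evaluated=0,
            )
    assert best is not None
    best.combos_evaluated = combos
    return best


def brute_force_score(
    net: PhyloNetwork,
    site: Mapping[int, int | None],
    cost: CostMatrix,
    *,
    edge_weights: Mapping[tuple[int, int], float] | None = None,
    max_combos: int = MAX_BRUTE_COMBOS,
) -> OptimumResult:
    """Exhaustive minimization of the edge-sum over every extension that
    agrees with the leaf assignment (missing leaves are free variables).

    Testing oracle only; vectorized over all ``k^m`` combinations where
    ``m`` counts the unconstrained vertices.
    """
    k = cost.k
    fixed: dict[int, int] = {}
    free: list[int] = []
    for v in net.vertices:
        if net.out_degree(v) == 0:
            st = site[net.label_of(v)]
            if st is None:
                free.append(v)
            else:
                fixed[v] = st
        else:
            free.append(v)
    m = len(free)
    n_combos = k**m
    if n_combos > max_combos:
        raise NetworkError(
            f"{n_combos} extensions exceed the brute-force guard ({max_combos})"
        )
    # state of free vertex #idx across all combinations (mixed-radix digits)
    digits = {
        v: ((np.arange(n_combos) // k ** (m - 1 - i)) % k).astype(np.int16)
        for i, v in enumerate(free)
    }
    total = np.zeros(n_combos)
    for (u, v) in net.edges:
        C = cost.costs
        if edge_weights is not None:
            C = edge_weights.get((u, v), 1.0) * C
        su = digits[u] if u in digits else fixed[u]
        sv = digits[v] if v in digits else fixed[v]
        total = total + C[su, sv]
    best_idx = int(total.argmin())
    ext = dict(fixed)
    for i, v in enumerate(free):
        ext[v] = int((best_idx // k ** (m - 1 - i)) % k)
    pins = {w: ext[w] for w in net.reticulations}
    score = evaluate_p2(net, ext, cost, edge_weights=edge_weights)
    return OptimumResult(
        score=score, extension=ext, pinned_states=pins, combos_evaluated=n_combos
    )
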