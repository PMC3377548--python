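"""Shared fixtures: reference networks and seeded random corpora."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from netparsimony import (
    CostMatrix,
    GeneratorConfig,
    PhyloNetwork,
    fixture,
    random_characters,
    random_cost_matrix,
    random_network,
)


@pytest.fixture
def cherry() -> PhyloNetwork:
    return fixture("CHERRY")


@pytest.fixture
def fig1l() -> PhyloNetwork:
    return fixture("FIG1L")


@pytest.fixture
def fig1r() -> PhyloNetwork:
    return fixture("FIG1R")


@dataclass(frozen=True)
class Instance:
    net: PhyloNetwork
    site: dict[int, int]
    cost: CostMatrix
    tag: str


def make_corpus(
    ns=(3, 4, 5, 6),
    rs=(0, 1, 2),
    ks=(2, 3),
    cost_modes=("unit", "integer"),
    seeds=(0,),
    *,
    no_sister: bool = False,
) -> list[Instance]:
    """A deterministic grid of random scoring instances."""
    out = []
    for n in ns:
        for r in rs:
            if no_sister and n == 3 and r == 2:
                # three leaves cannot host two non-sister, time-consistent
                # reticulations under edge-pair subdivision
                continue
            for k in ks:
                for mode in cost_modes:
                    for seed in seeds:
                        base = 1000 * n + 100 * r + 10 * k + seed
                        cfg = GeneratorConfig(
                            n=n, r=r, k=k, seed=base, require_no_sister=no_sister
                        )
                        net = random_network(cfg)
                        site = random_characters(net, k, 1, base + 1).site(0)
                        cost = random_cost_matrix(k, base + 2, mode)
                        out.append(
                            Instance(net, site, cost, f"n{n}r{r}k{k}{mode}s{seed}")
                        )
    return out


@pytest.fixture(scope="session")
def small_corpus() -> list[Instance]:
    return make_corpus()


@pytest.fixture(scope="session")
def no_sister_corpus() -> list[Instance]:
    return make_corpus(cost_modes=("unit",), no_sister=True)
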