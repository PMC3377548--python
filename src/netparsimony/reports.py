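"""JSON-serializable scoring reports.

One report covers every requested method on every site of a character
matrix, with per-site records and aggregate sums (the parsimony score is
site-separable, so per-site bounds and optima add)."""

from __future__ import annotations

from typing import Mapping

from . import __version__
from .exact import exact_score
from .fitch import fitch_displayed_bounds, fitch_network
from .displayed import score_p1_exhaustive
from .network import PhyloNetwork, has_sister_reticulations
from .sankoff import CostMatrix, LeafAssignment, majority_upper_bound, sankoff_bounds

__all__ = ["build_report", "METHODS"]

METHODS = ("sankoff", "fitch", "exact", "p1", "majority")

SCHEMA = "netparsimony-report/1"


def _ext_json(ext: Mapping[int, int]) -> dict[str, int]:
    return {str(v): int(s) for v, s in sorted(ext.items())}


def _score_site(
    net: PhyloNetwork,
    site: Mapping[int, int | None],
    cost: CostMatrix,
    methods: tuple[str, ...],
) -> dict:
    rec: dict = {}
    if "sankoff" in methods:
        res = sankoff_bounds(net, site, cost)
        rec["sankoff"] = {
            "lower": res.lower,
            "upper": res.upper,
            "conflicts": [
                {
                    "vertex": c.vertex,
                    "parents": list(c.parents),
                    "states": list(c.states),
                    "assigned": c.assigned,
                }
                for c in res.conflicts
            ],
            "extension": _ext_json(res.extension),
        }
    if "fitch" in methods:
        fr = fitch_network(net, site)
        entry = {
            "ub": fr.ub,
            "upper": fr.direct_score,
            "extension": _ext_json(fr.extension),
            "unit_cost": True,
        }
        if not has_sister_reticulations(net):
            lo, up, _ = fitch_displayed_bounds(net, site)
            entry["displayed_lower"] = lo
            entry["displayed_upper"] = up
        rec["fitch"] = entry
    if "exact" in methods:
        res = exact_score(net, site, cost)
        rec["exact"] = {
            "optimum": res.score,
            "extension": _ext_json(res.extension),
            "pinned_states": _ext_json(res.pinned_states),
            "combos_evaluated": res.combos_evaluated,
        }
    if "p1" in methods:
        score, idx, ext = score_p1_exhaustive(net, site, cost)
        rec["p1"] = {"score": score, "tree_index": idx, "extension": _ext_json(ext)}
    if "majority" in methods:
        up, ext = majority_upper_bound(net, site, cost)
        rec["majority"] = {"upper": up, "extension": _ext_json(ext)}
    return rec


def build_report(
    net: PhyloNetwork,
    chars: LeafAssignment,
    cost: CostMatrix,
    methods: tuple[str, ...] | str = METHODS,
    *,
    provenance: Mapping | None = None,
) -> dict:
    """Score every site with every requested method."""
    if isinstance(methods, str):
        methods = METHODS if methods == "all" else (methods,)
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    sites = [
        _score_site(net, chars.site(s), cost, tuple(methods))
        for s in range(chars.sites)
    ]
    aggregate: dict = {}
    for m in methods:
        totals: dict[str, float] = {}
        for rec in sites:
            for key, val in rec[m].items():
                if isinstance(val, (int, float)) and not isinstance(val, bool):
                    totals[key] = totals.get(key, 0) + val
        aggregate[m] = totals
    return {
        "schema": SCHEMA,
        "provenance": {"version": __version__, **(dict(provenance or {}))},
        "network": {"n": net.n, "r": net.r, "root": net.root},
        "sites": sites,
        "aggregate": aggregate,
    }
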