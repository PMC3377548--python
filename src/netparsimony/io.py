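"""Reading and writing networks, characters and cost matrices.

Two network formats are supported:

``edgelist``
    One ``child<TAB>parent`` pair per line under a header, integer vertex
    ids.  The root is the unique id never appearing as a child.  This is
    the unambiguous interchange format (vertex ids survive round trips).

``enewick``
    Extended Newick: a rooted Newick string in which each reticulate
    vertex appears twice under a shared ``#H<id>`` tag, the first
    occurrence carrying its child subtree.  Internal integer labels are
    optional; absent ones are auto-assigned deterministically.

Characters arrive as a TSV with header ``leaf<TAB>site1...`` (``?`` =
missing), cost matrices as a CSV whose first row and column hold the state
symbols.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import NetworkError, PhyloNetwork, validate_structure
from .sankoff import CostMatrix, LeafAssignment

__all__ = [
    "read_network",
    "write_network",
    "parse_enewick",
    "to_enewick",
    "read_characters",
    "write_characters",
    "read_cost_matrix",
    "write_cost_matrix",
    "ParseError",
]


class ParseError(NetworkError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# edge list
# ---------------------------------------------------------------------------


def _parse_edgelist(text: str) -> PhyloNetwork:
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise ParseError("empty edge list")
    start = 1 if lines[0].lower().replace(" ", "").startswith("child") else 0
    edges: list[tuple[int, int]] = []
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        parts = ln.split()
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: expected 'child<TAB>parent', got {ln!r}")
        try:
            child, parent = int(parts[0]), int(parts[1])
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer vertex id in {ln!r}") from None
        if (parent, child) in edges:
            raise ParseError(f"line {lineno}: duplicate edge ({parent}, {child})")
        edges.append((parent, child))
    try:
        net = PhyloNetwork(edges)
    except NetworkError as exc:
        raise ParseError(str(exc)) from exc
    import networkx as nx

    if not nx.is_directed_acyclic_graph(net.graph):
        raise ParseError("edge list describes a cyclic graph")
    return net


def _format_edgelist(net: PhyloNetwork) -> str:
    lines = ["child\tparent"]
    for parent, child in sorted(net.edges, key=lambda e: (e[1], e[0])):
        lines.append(f"{child}\t{parent}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# extended Newick
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    name: int | None = None
    tag: str | None = None
    children: list["_Node"] = field(default_factory=list)


def _tokenize_label(s: str, pos: int) -> tuple[str, int]:
    out = []
    while pos < len(s) and s[pos] not in "(),;":
        out.append(s[pos])
        pos += 1
    return "".join(out), pos


def _parse_subtree(s: str, pos: int) -> tuple[_Node, int]:
    node = _Node()
    if pos < len(s) and s[pos] == "(":
        pos += 1
        while True:
            child, pos = _parse_subtree(s, pos)
            node.children.append(child)
            if pos >= len(s):
                raise ParseError(f"column {pos}: unterminated subtree")
            if s[pos] == ",":
                pos += 1
                continue
            if s[pos] == ")":
                pos += 1
                break
            raise ParseError(f"column {pos}: expected ',' or ')', got {s[pos]!r}")
    label, pos = _tokenize_label(s, pos)
    label = label.strip()
    if "#" in label:
        name, tag = label.split("#", 1)
        if not tag.upper().startswith("H") or not tag[1:].isdigit():
            raise ParseError(f"bad hybrid tag {tag!r}")
        node.tag = tag.upper()
        node.name = int(name) if name else None
    elif label:
        try:
            node.name = int(label)
        except ValueError:
            raise ParseError(
                f"vertex label {label!r} is not an integer"
            ) from None
    if not node.children and node.name is None and node.tag is None:
        raise ParseError(f"column {pos}: empty subtree")
    return node, pos


def parse_enewick(text: str) -> PhyloNetwork:
    """Parse an extended-Newick string into a network."""
    s = "".join(text.split())
    if not s:
        raise ParseError("empty eNewick input")
    if not s.endswith(";"):
        raise ParseError("eNewick string must end with ';'")
    root, pos = _parse_subtree(s, 0)
    if pos != len(s) - 1:
        raise ParseError(f"column {pos}: trailing characters after subtree")

    used: set[int] = set()

    def collect(nd: _Node) -> None:
        if nd.name is not None:
            used.add(nd.name)
        for c in nd.children:
            collect(c)

    collect(root)
    counter = max(used, default=0)
    tag_id: dict[str, int] = {}
    tag_named: dict[str, int] = {}

    def scan_names(nd: _Node) -> None:
        if nd.tag is not None and nd.name is not None:
            prev = tag_named.get(nd.tag)
            if prev is not None and prev != nd.name:
                raise ParseError(
                    f"hybrid tag {nd.tag} labelled inconsistently ({prev} vs {nd.name})"
                )
            tag_named[nd.tag] = nd.name
        for c in nd.children:
            scan_names(c)

    scan_names(root)

    def vid(nd: _Node) -> int:
        nonlocal counter
        if nd.tag is not None:
            if nd.tag in tag_named:
                return tag_named[nd.tag]
            if nd.tag not in tag_id:
                counter += 1
                tag_id[nd.tag] = counter
            return tag_id[nd.tag]
        if nd.name is None:
            counter += 1
            nd.name = counter
        return nd.name

    edges: list[tuple[int, int]] = []
    child_order: dict[int, list[int]] = {}

    def walk(nd: _Node) -> int:
        me = vid(nd)
        if nd.children:
            kids = [walk(c) for c in nd.children]
            for c in kids:
                if (me, c) in edges:
                    raise ParseError(f"duplicate edge ({me}, {c})")
                edges.append((me, c))
            child_order.setdefault(me, []).extend(kids)
        return me

    walk(root)
    orders = {
        v: tuple(kids)
        for v, kids in child_order.items()
        if list(kids) != sorted(kids)
    }
    try:
        net = PhyloNetwork(edges, child_order=orders)
    except NetworkError as exc:
        raise ParseError(str(exc)) from exc
    import networkx as nx

    if not nx.is_directed_acyclic_graph(net.graph):
        raise ParseError("eNewick string describes a cyclic graph")
    return net


def to_enewick(net: PhyloNetwork, *, internal_labels: bool = True) -> str:
    """Serialize a network as extended Newick.

    With ``internal_labels`` (default) all vertex ids are written, so a
    round trip restores the identical network; without it only leaves and
    hybrid tags carry labels and the round trip is isomorphic.
    """
    tags: dict[int, int] = {}
    for i, w in enumerate(net.reticulations, start=1):
        tags[w] = i
    written: set[int] = set()

    def render(v: int) -> str:
        label = ""
        if net.out_degree(v) == 0:
            label = str(net.label_of(v))
        elif internal_labels:
            label = str(v)
        if net.is_reticulate(v):
            if v in written:
                return f"{label}#H{tags[v]}"
            written.add(v)
            inner = ",".join(render(w) for w in net.children(v))
            return f"({inner}){label}#H{tags[v]}"
        if net.out_degree(v) == 0:
            return label
        inner = ",".join(render(w) for w in net.children(v))
        return f"({inner}){label}"

    return render(net.root) + ";"


# ---------------------------------------------------------------------------
# front doors
# ---------------------------------------------------------------------------


def _sniff(text: str) -> str:
    head = text.lstrip()
    return "enewick" if head.startswith("(") else "edgelist"


def read_network(path: str | Path, format: str = "auto") -> PhyloNetwork:
    """Read a network from ``path`` in ``edgelist`` or ``enewick`` format
    (``auto`` sniffs from the first character)."""
    text = Path(path).read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    fmt = _sniff(text) if format == "auto" else format
    if fmt == "edgelist":
        return _parse_edgelist(text)
    if fmt == "enewick":
        return parse_enewick(text)
    raise ValueError(f"unknown network format {format!r}")


def write_network(
    net: PhyloNetwork, path: str | Path, format: str = "edgelist"
) -> None:
    if format == "edgelist":
        Path(path).write_text(_format_edgelist(net))
    elif format == "enewick":
        Path(path).write_text(to_enewick(net) + "\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_characters(
    path: str | Path,
    alphabet: Sequence[str],
    net: PhyloNetwork | None = None,
) -> LeafAssignment:
    """Read a TSV character matrix and resolve symbols against ``alphabet``.

    With ``net`` given, the leaf column is checked against the network's
    leaf labels.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "leaf":
        raise ParseError(f"{path}: first column must be 'leaf'")
    rows = {}
    for _, row in df.iterrows():
        try:
            label = int(row.iloc[0])
        except ValueError:
            raise ParseError(f"{path}: non-integer leaf id {row.iloc[0]!r}") from None
        rows[label] = [str(x) for x in row.iloc[1:]]
    if net is not None:
        expected = set(net.leaf_labels.values())
        got = set(rows)
        if expected != got:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ParseError(
                f"{path}: leaf set mismatch (missing {missing}, unknown {extra})"
            )
    return LeafAssignment.from_symbols(rows, alphabet)


def write_characters(
    chars: LeafAssignment, alphabet: Sequence[str], path: str | Path
) -> None:
    cols = [f"site{i + 1}" for i in range(chars.sites)]
    buf = _stdio.StringIO()
    buf.write("leaf\t" + "\t".join(cols) + "\n")
    for label in sorted(chars.data):
        syms = [
            "?" if st is None else alphabet[st] for st in chars.data[label]
        ]
        buf.write(str(label) + "\t" + "\t".join(syms) + "\n")
    Path(path).write_text(buf.getvalue())


def read_cost_matrix(path: str | Path) -> CostMatrix:
    """Read a CSV cost matrix with state symbols in the first row/column."""
    df = pd.read_csv(path, index_col=0)
    symbols = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != symbols:
        raise ParseError(f"{path}: row and column symbols disagree")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ParseError(f"{path}: non-numeric entries in cost matrix")
    try:
        return CostMatrix(symbols, values)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_cost_matrix(cost: CostMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cost.costs, index=cost.alphabet, columns=cost.alphabet)
    df.to_csv(path)


def strict_validate(net: PhyloNetwork):
    """Full structural validation (used by --strict CLI mode)."""
    from .network import validate_time_consistency

    rep = validate_structure(net)
    if rep.is_valid("dag"):
        rep = rep.merged_with(validate_time_consistency(net))
    return rep
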