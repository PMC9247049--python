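"""Readers and writers for edge lists, GML graphs and community covers.

Edge lists are whitespace-delimited, one edge per line, ``#`` comments
ignored; an optional third column (a weight) is ignored.  Community files
follow the one-community-per-line convention ("cmty" files): members
whitespace-delimited, optional leading ``label:`` token naming the
community, otherwise the 1-based line number is the label.
"""

from __future__ import annotations

import os
from importlib import resources
from typing import Optional, Tuple, Union

import networkx as nx

from .graph import Cover, Graph, GraphFormatError

PathOrText = Union[str, os.PathLike]


def _as_text(source: PathOrText) -> str:
    """Treat the argument as a path if it names a file, else as raw text."""
    s = os.fspath(source)
    if "\n" not in s and os.path.exists(s):
        with open(s) as fh:
            return fh.read()
    return s


def _coerce(token: str):
    """Edge-list tokens that look like integers become integers."""
    try:
        return int(token)
    except ValueError:
        return token


def read_graph(source: PathOrText, format: str = "edgelist") -> Graph:
    """Read a :class:`Graph` from an edge-list or GML file (or raw text).

    Raises :class:`GraphFormatError` naming the offending line on parse
    failure, and on an empty graph.
    """
    text = _as_text(source)
    if format == "edgelist":
        edges = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise GraphFormatError(
                    f"line {lineno}: expected 'u v [w]', got {line!r}")
            edges.append((_coerce(parts[0]), _coerce(parts[1])))
        if not edges:
            raise GraphFormatError("empty graph: no edges found")
        return Graph(edges)
    if format == "gml":
        try:
            g = nx.parse_gml(text, label="label")
        except Exception as exc:
            raise GraphFormatError(f"GML parse failure: {exc}") from exc
        return Graph(g.edges(), nodes=g.nodes())
    raise GraphFormatError(f"unknown graph format {format!r}")


def write_graph(graph: Graph) -> str:
    """Edge-list text; round-trips through :func:`read_graph`."""
    return "".join(f"{u} {v}\n" for u, v in graph.edges())


def read_cover(source: PathOrText, graph: Optional[Graph] = None) -> Cover:
    """Read a cover, one community per line.

    When ``graph`` is given, members must be nodes of the graph.
    """
    text = _as_text(source)
    communities = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label: object = lineno
        if ":" in line.split()[0]:
            head, _, rest = line.partition(":")
            label, line = _coerce(head), rest
        members = frozenset(_coerce(t) for t in line.split())
        if not members:
            raise GraphFormatError(f"line {lineno}: empty community")
        if graph is not None:
            foreign = [v for v in members if v not in graph]
            if foreign:
                raise GraphFormatError(
                    f"line {lineno}: member(s) {foreign!r} not in graph")
        if label in communities:
            raise GraphFormatError(f"line {lineno}: duplicate label {label!r}")
        communities[label] = members
    if not communities:
        raise GraphFormatError("no communities found")
    return Cover(communities)


def write_cover(cover: Cover, fuzzy: bool = False) -> str:
    """Serialize a cover.

    Crisp form: one community per line, members sorted.  Fuzzy form:
    tab-separated (node, community, coefficient) rows, coefficients to six
    decimals; requires the cover to carry coefficients.
    """
    from .graph import label_key
    if fuzzy:
        if cover.coefficients is None:
            raise ValueError("fuzzy output requested but cover has no "
                             "membership coefficients")
        rows = []
        for v in cover.nodes:
            for c in cover.memberships(v):
                rows.append(f"{v}\t{c}\t{cover.coefficients[v][c]:.6f}")
        return "\n".join(rows) + "\n"
    lines = []
    for c in cover.labels:
        members = sorted(cover.communities[c], key=label_key)
        lines.append(" ".join(str(v) for v in members))
    return "\n".join(lines) + "\n"


def karate_fixture() -> Tuple[Graph, Cover]:
    """The Zachary karate club (34 nodes, 78 edges, 1-based labels) and its
    two-faction ground truth (instructor vs. administrator)."""
    data = resources.files("gamecover.data")
    graph = read_graph((data / "zachary_karate.edges").read_text())
    truth = read_cover((data / "zachary_karate.cmty").read_text(), graph=graph)
    return graph, truth
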