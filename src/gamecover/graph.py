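"""Undirected simple graphs and community covers.

The :class:`Graph` container is deliberately minimal: the detection game only
ever needs neighbor sets, degrees and the edge count, so the graph is stored
as a mapping from node to a frozen neighbor set.  Node identifiers (integers
or strings) are preserved verbatim; every public output uses the caller's
identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Hashable, Iterable, List, Mapping, Optional, Tuple

logger = logging.getLogger(__name__)

Node = Hashable
Label = Hashable


def label_key(x: Label):
    """Fixed total order on node/community labels (ints before strings)."""
    return (isinstance(x, str), x)


class GraphFormatError(ValueError):
    """Raised when an input file or text cannot be parsed as a graph/cover."""


class Graph:
    """Undirected simple graph: no self-loops, no multi-edges.

    Parameters
    ----------
    edges:
        Iterable of node pairs. Duplicate edges (in either orientation) and
        self-loops are dropped with a logged warning.
    nodes:
        Optional extra nodes (possibly isolated) to include.
    """

    __slots__ = ("_adj", "_m")

    def __init__(self, edges: Iterable[Tuple[Node, Node]],
                 nodes: Iterable[Node] = ()) -> None:
        adj: Dict[Node, set] = {v: set() for v in nodes}
        m = 0
        dropped_loops = dropped_dups = 0
        for u, v in edges:
            if u == v:
                dropped_loops += 1
                continue
            adj.setdefault(u, set())
            adj.setdefault(v, set())
            if v in adj[u]:
                dropped_dups += 1
                continue
            adj[u].add(v)
            adj[v].add(u)
            m += 1
        if dropped_loops or dropped_dups:
            logger.warning("dropped %d self-loop(s) and %d duplicate edge(s)",
                           dropped_loops, dropped_dups)
        if not adj:
            raise GraphFormatError("empty graph: no nodes or edges supplied")
        self._adj: Dict[Node, FrozenSet[Node]] = {
            v: frozenset(nbrs) for v, nbrs in adj.items()
        }
        self._m = m

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self._adj)

    @property
    def m(self) -> int:
        return self._m

    @property
    def nodes(self) -> List[Node]:
        """Nodes in a deterministic (sorted) order."""
        return sorted(self._adj, key=label_key)

    def __contains__(self, v: Node) -> bool:
        return v in self._adj

    def __iter__(self):
        return iter(self.nodes)

    def neighbors(self, v: Node) -> FrozenSet[Node]:
        try:
            return self._adj[v]
        except KeyError:
            raise KeyError(f"node {v!r} not in graph") from None

    def degree(self, v: Node) -> int:
        return len(self.neighbors(v))

    def has_edge(self, u: Node, v: Node) -> bool:
        return v in self._adj.get(u, ())

    def edges(self) -> List[Tuple[Node, Node]]:
        """Each edge once, endpoints and list in sorted order."""
        out = []
        for u in self._adj:
            for v in self._adj[u]:
                if label_key(u) < label_key(v):
                    out.append((u, v))
        out.sort(key=lambda e: (label_key(e[0]), label_key(e[1])))
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"Graph(n={self.n}, m={self.m})"


@dataclass(frozen=True)
class Cover:
    """A community cover: communities as node sets, nodes may repeat.

    A partition is the special case where every node has exactly one
    membership.  ``coefficients`` optionally carries fuzzy membership weights
    alpha[node][community]; when present they are positive exactly on the
    (node, community) memberships and sum to 1 per node.
    """

    communities: Mapping[Label, FrozenSet[Node]]
    coefficients: Optional[Mapping[Node, Mapping[Label, float]]] = field(
        default=None)

    def __post_init__(self):
        comms = {c: frozenset(members) for c, members in
                 self.communities.items()}
        object.__setattr__(self, "communities", comms)
        if not comms:
            raise ValueError("a cover must contain at least one community")
        if self.coefficients is not None:
            coeff = {v: dict(row) for v, row in self.coefficients.items()}
            object.__setattr__(self, "coefficients", coeff)
            for v in self.nodes:
                row = coeff.get(v, {})
                if set(row) != set(self.memberships(v)):
                    raise ValueError(
                        f"coefficients for node {v!r} do not match memberships")
                total = sum(row.values())
                if any(a <= 0 for a in row.values()) or abs(total - 1) > 1e-6:
                    raise ValueError(
                        f"coefficients for node {v!r} must be positive and "
                        f"sum to 1 (got {total:.6g})")

    # -- accessors -------------------------------------------------------
    @property
    def nodes(self) -> List[Node]:
        seen = set()
        for members in self.communities.values():
            seen.update(members)
        return sorted(seen, key=label_key)

    @property
    def labels(self) -> List[Label]:
        return sorted(self.communities, key=label_key)

    def memberships(self, v: Node) -> List[Label]:
        return [c for c in self.labels if v in self.communities[c]]

    def membership_map(self) -> Dict[Node, List[Label]]:
        out: Dict[Node, List[Label]] = {}
        for c in self.labels:
            for v in self.communities[c]:
                out.setdefault(v, []).append(c)
        return out

    def is_partition(self) -> bool:
        return all(len(ms) == 1 for ms in self.membership_map().values())

    def overlapping_nodes(self) -> List[Node]:
        return sorted((v for v, ms in self.membership_map().items()
                       if len(ms) >= 2), key=label_key)

    def as_sets(self) -> List[FrozenSet[Node]]:
        return [self.communities[c] for c in self.labels]

    def uniform_coefficients(self) -> "Cover":
        """Crisp cover -> fuzzy cover with alpha = 1/#memberships per node."""
        if self.coefficients is not None:
            return self
        coeff = {v: {c: 1.0 / len(ms) for c in ms}
                 for v, ms in self.membership_map().items()}
        return Cover(self.communities, coeff)

    def __repr__(self) -> str:  # pragma: no cover
        k = len(self.communities)
        ov = len(self.overlapping_nodes())
        return f"Cover(communities={k}, nodes={len(self.nodes)}, overlapping={ov})"
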