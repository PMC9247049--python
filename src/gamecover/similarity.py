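"""Neighborhood-overlap similarity indices.

Five classical local indices over open neighborhoods (a node is never its
own neighbor): Jaccard (JC), Salton/cosine (SI), Sorensen (SO),
hub-promoted (HP) and hub-depressed (HD).  The detection game weights each
neighbor's contribution by (1 + sim), so structurally similar neighbors
pull harder.  HP is the default metric.

For any pair with nonzero common neighborhood the indices are totally
ordered, JC <= HD <= SO <= SI <= HP, because the denominators satisfy
|union| >= max >= (|G_i|+|G_j|)/2 >= sqrt(|G_i||G_j|) >= min.
"""

from __future__ import annotations

import math
from typing import Dict, Tuple

from .graph import Graph, Node

METRICS = ("JC", "SI", "SO", "HP", "HD")
DEFAULT_METRIC = "HP"


def similarity(graph: Graph, i: Node, j: Node, metric: str = DEFAULT_METRIC) -> float:
    """Similarity index of a node pair; 0 whenever a denominator vanishes."""
    name = metric.upper()
    if name not in METRICS:
        raise ValueError(f"unknown similarity metric {metric!r}; "
                         f"choose one of {METRICS}")
    gi, gj = graph.neighbors(i), graph.neighbors(j)
    if not gi or not gj:
        return 0.0
    inter = len(gi & gj)
    if inter == 0:
        return 0.0
    if name == "JC":
        return inter / len(gi | gj)
    if name == "SI":
        return inter / math.sqrt(len(gi) * len(gj))
    if name == "SO":
        return 2 * inter / (len(gi) + len(gj))
    if name == "HP":
        return inter / min(len(gi), len(gj))
    return inter / max(len(gi), len(gj))  # HD


def similarity_cache(graph: Graph, metric: str = DEFAULT_METRIC
                     ) -> Dict[Tuple[Node, Node], float]:
    """Precomputed similarity for every adjacent pair, keyed both ways.

    The game's utility only ever evaluates sim on edges (interactions are
    local), so one pass over the edge list suffices.
    """
    cache: Dict[Tuple[Node, Node], float] = {}
    for u, v in graph.edges():
        s = similarity(graph, u, v, metric)
        cache[(u, v)] = s
        cache[(v, u)] = s
    return cache
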