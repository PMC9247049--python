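"""Evaluation metrics for overlapping community structure.

Three complementary views:

* :func:`q_ov` — overlapping modularity, a fuzzy-membership generalization
  of Newman modularity.  Belonging coefficients alpha[i][c] in [0,1] (one
  row per node, summing to 1) are passed through a sharp logistic transfer
  F(a, b) = sigma(f(a)) * sigma(f(b)), f(x) = 2px - p, so that near-crisp
  memberships approach the 0/1 indicator and Q_ov approaches classical
  modularity.  Sharpness defaults to p = 30.
* :func:`overlapping_nmi` — normalized mutual information between two
  covers, built from per-community binary membership variables with
  best-match conditional entropies, normalized by max(H(X), H(Y)).
* :func:`avg_f1` — symmetric average of best-match F1 scores between the
  community sets of the two covers.

All metrics are pure functions of their inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np

from .graph import Cover, Graph


@dataclass(frozen=True)
class QovParams:
    """Logistic sharpness of the belonging-coefficient transfer; larger p
    pushes the transfer toward a hard 0/1 indicator."""

    p: float = 30.0
    printed_sign: bool = False  # use the inverted transfer 1/(1+e^{+f})

    def __post_init__(self):
        if self.p <= 0:
            raise ValueError("sharpness p must be positive")


def _logistic(x: np.ndarray, params: QovParams) -> np.ndarray:
    f = 2.0 * params.p * x - params.p
    if params.printed_sign:
        return 1.0 / (1.0 + np.exp(f))
    return 1.0 / (1.0 + np.exp(-f))


def q_ov(graph: Graph, cover: Cover, params: QovParams = QovParams()) -> float:
    """Overlapping modularity of a cover on an undirected graph.

    Crisp covers are first given uniform coefficients alpha = 1/#memberships.
    For community c with transferred memberships L_i = sigma(f(alpha_ic)),
    the observed term sums F(alpha_ic, alpha_jc) = L_i L_j over adjacent
    pairs and the null term pairs expected stubs L_i mean(L) k_i, exactly as
    classical modularity pairs k_i k_j / 2m.  With one all-inclusive crisp
    community the transfer saturates and Q_ov collapses to the classical
    modularity of the trivial partition, i.e. 0.
    """
    if graph.m == 0:
        raise ValueError("Q_ov is undefined on an edgeless graph")
    cover = cover.uniform_coefficients()
    nodes = graph.nodes
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    degrees = np.array([graph.degree(v) for v in nodes], dtype=float)
    two_m = 2.0 * graph.m
    coeff = cover.coefficients
    for v in nodes:
        row = coeff.get(v)
        if row is not None and abs(sum(row.values()) - 1.0) > 1e-6:
            raise ValueError(f"coefficients of node {v!r} do not sum to 1")
    edges = graph.edges()
    ui = np.array([index[u] for u, _ in edges], dtype=int)
    vi = np.array([index[v] for _, v in edges], dtype=int)
    total = 0.0
    for c in cover.labels:
        alpha = np.zeros(n)
        for v in cover.communities[c]:
            if v in index:
                alpha[index[v]] = coeff[v][c]
        L = _logistic(alpha, params)
        observed = 2.0 * float(np.sum(L[ui] * L[vi]))  # both orientations
        expected_stub = float(np.mean(L)) * L * degrees
        null = float(np.sum(expected_stub)) ** 2 / two_m
        total += observed - null
    return total / two_m


# ---------------------------------------------------------------------------
# Overlapping NMI
# ---------------------------------------------------------------------------

def _h(p: float) -> float:
    return -p * math.log2(p) if p > 0 else 0.0


def _pair_entropies(a: frozenset, b: frozenset, n: int):
    """Joint entropy terms of two binary membership indicators."""
    p11 = len(a & b) / n
    p10 = len(a - b) / n
    p01 = len(b - a) / n
    p00 = 1.0 - p11 - p10 - p01
    return p11, p10, p01, p00


def _conditional_entropy(a: frozenset, bs: Sequence[frozenset], n: int) -> float:
    """H(X_a | Y) = min over communities b of H(X_a | X_b), restricted to
    pairs where the matched (1,1)/(0,0) cells dominate; unmatched falls back
    to the unconditional entropy H(X_a)."""
    ha = _h(len(a) / n) + _h(1 - len(a) / n)
    best = ha
    for b in bs:
        p11, p10, p01, p00 = _pair_entropies(a, b, n)
        if _h(p11) + _h(p00) < _h(p10) + _h(p01):
            continue  # b explains a no better than chance
        hb = _h(len(b) / n) + _h(1 - len(b) / n)
        joint = _h(p11) + _h(p10) + _h(p01) + _h(p00)
        best = min(best, joint - hb)
    return best


def overlapping_nmi(cover_a: Cover, cover_b: Cover) -> float:
    """NMI between two covers over the same node universe, in [0, 1].

    Each community is a binary membership variable over the nodes; the
    information one cover carries about the other is accumulated through
    best-match conditional entropies and normalized by the larger total
    entropy: NMI = I(X:Y) / max(H(X), H(Y)), where
    I = ((H(X) - H(X|Y)) + (H(Y) - H(Y|X))) / 2.  Identical covers score 1;
    covers carrying no information about each other (e.g. all singletons
    vs. one all-inclusive community) score 0.
    """
    na, nb = set(cover_a.nodes), set(cover_b.nodes)
    if na != nb:
        raise ValueError("covers are over different node universes")
    n = len(na)
    xs, ys = cover_a.as_sets(), cover_b.as_sets()
    hx = sum(_h(len(a) / n) + _h(1 - len(a) / n) for a in xs)
    hy = sum(_h(len(b) / n) + _h(1 - len(b) / n) for b in ys)
    if max(hx, hy) == 0:
        return 1.0  # both covers are trivial and identical in information
    hxy = sum(_conditional_entropy(a, ys, n) for a in xs)
    hyx = sum(_conditional_entropy(b, xs, n) for b in ys)
    mutual = 0.5 * ((hx - hxy) + (hy - hyx))
    return mutual / max(hx, hy)


# ---------------------------------------------------------------------------
# Average F1
# ---------------------------------------------------------------------------

def _f1(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    precision = inter / len(a)
    recall = inter / len(b)
    return 2 * precision * recall / (precision + recall)


def avg_f1(cover_a: Cover, cover_b: Cover) -> float:
    """Symmetric average of best-match F1 between two covers' communities."""
    xs, ys = cover_a.as_sets(), cover_b.as_sets()
    if not xs or not ys:
        raise ValueError("covers must be nonempty")
    fwd = sum(max(_f1(a, b) for b in ys) for a in xs) / len(xs)
    bwd = sum(max(_f1(b, a) for a in xs) for b in ys) / len(ys)
    return 0.5 * (fwd + bwd)


# ---------------------------------------------------------------------------
# Cover summary statistics
# ---------------------------------------------------------------------------

def cover_stats(cover: Cover) -> Dict[str, object]:
    """Measured overlap statistics of a cover.

    Returns the overlapping-node fraction On, the mean membership count Om
    over overlapping nodes (0.0 for a partition), the community count and
    the community-size histogram (size -> number of communities).
    """
    memberships = cover.membership_map()
    n = len(memberships)
    overlapping = [len(ms) for ms in memberships.values() if len(ms) >= 2]
    sizes: Dict[int, int] = {}
    for members in cover.communities.values():
        sizes[len(members)] = sizes.get(len(members), 0) + 1
    return {
        "on": len(overlapping) / n if n else 0.0,
        "om_mean": sum(overlapping) / len(overlapping) if overlapping else 0.0,
        "n_communities": len(cover.communities),
        "size_histogram": dict(sorted(sizes.items())),
    }
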