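"""Phase one: non-cooperative best-response label switching.

Each node is a selfish agent whose strategy is a set of community labels;
in phase one strategies are single labels and agents may only switch.  The
utility of agent i holding strategy s_i is

    U(S_-i, s_i) = sum over neighbors j of (1 + sim_ij) |s_i ∩ s_j| / sqrt(|s_j|)

so an agent is rewarded for sharing labels with neighbors, more so with
structurally similar ones.  Starting from singleton communities, agents
repeatedly adopt the best-response label among those held in their
neighborhood.  Sweeps visit nodes in a fixed degree order and apply updates
sequentially, so the dynamics are fully deterministic.

The sweep loop stops once the population of fixed agents (agents whose
label survived the last sweep) stops growing appreciably: with n_fixed
agents fixed after the previous sweep, the run stops when the increase is
at most epsilon * n_fixed.  epsilon = 0 demands no growth at all and, run
to quiescence, yields a Nash-stable labeling; small positive epsilon
(default 0.01) trades a little accuracy for earlier termination on graphs
where a few agents oscillate indefinitely.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Set, Tuple

from .graph import Cover, Graph, Label, Node, label_key
from .similarity import DEFAULT_METRIC, similarity_cache

logger = logging.getLogger(__name__)

#: Strategy profile: node -> set of community labels (singleton in phase one).
Profile = Dict[Node, Set[Label]]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable knobs of the two-phase detection game.

    epsilon:
        Stop-criterion slack in [0, 1); 0 means run to full quiescence.
    metric:
        Similarity index used inside the utility (JC, SI, SO, HP or HD).
    max_iterations:
        Safety cap on phase-one sweeps; hitting it is logged, not an error.
    phase_two_repeats:
        Number of synchronous overlap-expansion passes in phase two.
    order:
        Sweep order over nodes: "desc" (default) visits high-degree nodes
        first, "asc" low-degree first; ties broken by node identifier.
    """

    epsilon: float = 0.01
    metric: str = DEFAULT_METRIC
    max_iterations: int = 100
    phase_two_repeats: int = 2
    order: str = "desc"

    def __post_init__(self):
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must lie in [0, 1)")
        if self.max_iterations < 1 or self.phase_two_repeats < 1:
            raise ValueError("iteration counts must be positive")
        if self.order not in ("desc", "asc"):
            raise ValueError("order must be 'desc' or 'asc'")


@dataclass
class IterationTrace:
    """Per-sweep diagnostics of the phase-one dynamics."""

    n_fixed: List[int] = field(default_factory=list)
    switches: List[int] = field(default_factory=list)
    stop_reason: Optional[str] = None

    @property
    def iterations(self) -> int:
        return len(self.n_fixed)


def initialize(graph: Graph) -> Profile:
    """Every agent starts in its own singleton community, labeled by its
    node identifier."""
    return {v: {v} for v in graph}


def candidate_labels(graph: Graph, profile: Profile, i: Node) -> Set[Label]:
    """Labels agent i can imitate: every label in its neighborhood, plus its
    own current label(s)."""
    cands: Set[Label] = set(profile[i])
    for j in graph.neighbors(i):
        cands.update(profile[j])
    return cands


def payoff(graph: Graph, profile: Profile, simcache: Mapping, i: Node,
           candidate: Label) -> float:
    """Utility agent i would earn by playing the single label ``candidate``
    against the current profile of its neighbors."""
    if i not in graph:
        raise KeyError(f"node {i!r} not in graph")
    total = 0.0
    for j in graph.neighbors(i):
        sj = profile[j]
        if candidate in sj:
            total += (1.0 + simcache[(i, j)]) / math.sqrt(len(sj))
    return total


def candidate_payoffs(graph: Graph, profile: Profile, simcache: Mapping,
                      i: Node) -> Dict[Label, float]:
    """Utility of every candidate label of agent i, in one pass over its
    neighborhood (labels held by no neighbor earn 0)."""
    payoffs: Dict[Label, float] = {lab: 0.0 for lab in profile[i]}
    for j in graph.neighbors(i):
        sj = profile[j]
        w = (1.0 + simcache[(i, j)]) / math.sqrt(len(sj))
        for lab in sj:
            payoffs[lab] = payoffs.get(lab, 0.0) + w
    return payoffs


def best_response(graph: Graph, profile: Profile, simcache: Mapping,
                  i: Node) -> Label:
    """Best-response label of agent i.

    Ties: the current label wins if it attains the maximum (prevents
    oscillation); otherwise the smallest label under a fixed total order.
    """
    payoffs = candidate_payoffs(graph, profile, simcache, i)
    best = max(payoffs.values())
    (current,) = profile[i]
    if payoffs.get(current, 0.0) == best:
        return current
    return min((lab for lab, p in payoffs.items() if p == best),
               key=label_key)


def stop_check(n_fixed_prev: int, n_fixed_curr: int, epsilon: float) -> bool:
    """True when the fixed-agent count grew by at most epsilon * previous
    count; never fires while no agent is fixed yet."""
    if n_fixed_prev < 0 or n_fixed_curr < 0:
        raise ValueError("fixed-agent counts must be nonnegative")
    if n_fixed_prev == 0:
        return False
    return n_fixed_curr - n_fixed_prev <= epsilon * n_fixed_prev


def sweep_order(graph: Graph, order: str) -> List[Node]:
    sign = -1 if order == "desc" else 1
    return sorted(graph, key=lambda v: (sign * graph.degree(v), label_key(v)))


def run_phase_one(graph: Graph, config: DetectionConfig = DetectionConfig()
                  ) -> Tuple[Cover, IterationTrace]:
    """Run the label-switching game to a (near-)stable partition.

    Returns the partition grouping nodes by final label, plus the sweep
    trace.  Deterministic: no randomness anywhere in the dynamics.
    """
    simcache = similarity_cache(graph, config.metric)
    profile = initialize(graph)
    trace = IterationTrace()
    nodes = sweep_order(graph, config.order)
    n_fixed_prev = 0
    for _ in range(config.max_iterations):
        switches = 0
        fixed = 0
        for v in nodes:
            (old,) = profile[v]
            new = best_response(graph, profile, simcache, v)
            if new == old:
                fixed += 1
            else:
                profile[v] = {new}
                switches += 1
        trace.n_fixed.append(fixed)
        trace.switches.append(switches)
        if switches == 0:
            trace.stop_reason = "converged"
            break
        # epsilon = 0 demands full quiescence: the slackless criterion would
        # otherwise fire on a plateau while agents still switch, and the
        # result would not be Nash-stable
        if config.epsilon > 0 and stop_check(n_fixed_prev, fixed,
                                             config.epsilon):
            trace.stop_reason = "stop_criterion"
            break
        n_fixed_prev = fixed
    else:
        trace.stop_reason = "max_iterations"
        logger.warning("phase one hit the %d-sweep cap without meeting the "
                       "stop criterion", config.max_iterations)
    return profile_to_cover(profile), trace


def profile_to_cover(profile: Profile) -> Cover:
    communities: Dict[Label, set] = {}
    for v, labels in profile.items():
        for lab in labels:
            communities.setdefault(lab, set()).add(v)
    return Cover(communities)
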