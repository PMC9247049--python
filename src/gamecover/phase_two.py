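"""Phase two: per-agent overlap detection via RMS payoff thresholds.

Given the phase-one partition, each agent re-evaluates the utility of every
community label present in its neighborhood, normalizes the payoffs by the
best one, and computes a personal threshold: the root mean square of its
normalized payoffs.  Labels whose normalized payoff reaches the threshold
(inclusive) are added to the agent's strategy — labels are only ever added,
never removed, so the phase-one community of every node survives.  The
threshold is agent-specific: an agent pulled equally by two communities has
two normalized payoffs of 1 and threshold 1, so it joins both, while an
agent with one dominant community keeps a high threshold that foreign
labels rarely clear.

A pass is synchronous: every agent expands against the frozen pre-pass
profile, so the result is order-independent.  Repeating the pass (default
twice) lets chains of adjacent overlapping nodes be discovered: in the
second pass neighbors already holding several labels contribute attenuated
payoffs through the 1/sqrt(|s_j|) factor of the utility.

The final normalized payoffs also serve as fuzzy membership coefficients;
they are renormalized to sum to 1 per node for downstream metrics.
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Tuple

from .graph import Cover, Graph, Label, Node, label_key
from .phase_one import DetectionConfig, Profile, candidate_payoffs, profile_to_cover
from .similarity import similarity_cache


def payoff_threshold(normalized: List[float]) -> float:
    """Root mean square of a nonempty list of normalized payoffs."""
    if not normalized:
        raise ValueError("payoff_threshold needs at least one value")
    return math.sqrt(sum(x * x for x in normalized) / len(normalized))


def _cover_to_profile(cover: Cover) -> Profile:
    return {v: set(ms) for v, ms in cover.membership_map().items()}


def expand_once(graph: Graph, cover: Cover,
                config: DetectionConfig = DetectionConfig(),
                simcache: Mapping = None) -> Cover:
    """One synchronous overlap-expansion pass over all agents."""
    if simcache is None:
        simcache = similarity_cache(graph, config.metric)
    frozen = _cover_to_profile(cover)
    expanded: Profile = {}
    for v in graph:
        expanded[v] = set(frozen[v]) | set(
            _labels_above_threshold(graph, frozen, simcache, v))
    return profile_to_cover(expanded)


def _labels_above_threshold(graph: Graph, profile: Profile, simcache: Mapping,
                            v: Node) -> List[Label]:
    payoffs = candidate_payoffs(graph, profile, simcache, v)
    best = max(payoffs.values())
    if best <= 0.0:
        return []  # isolated in label space: nothing worth joining
    normalized = {lab: p / best for lab, p in payoffs.items()}
    thr = payoff_threshold(list(normalized.values()))
    return [lab for lab, x in normalized.items() if x >= thr]


def run_phase_two(graph: Graph, partition: Cover,
                  config: DetectionConfig = DetectionConfig()
                  ) -> Tuple[Cover, Dict[Node, Dict[Label, float]]]:
    """Apply ``config.phase_two_repeats`` expansion passes and attach fuzzy
    coefficients.

    Returns the crisp cover and, per node, the raw utilities of its retained
    labels renormalized to sum to 1 (a single-label node gets coefficient 1).
    """
    simcache = similarity_cache(graph, config.metric)
    cover = partition
    for _ in range(config.phase_two_repeats):
        cover = expand_once(graph, cover, config, simcache)
    profile = _cover_to_profile(cover)
    coefficients: Dict[Node, Dict[Label, float]] = {}
    for v in graph:
        labels = sorted(profile[v], key=label_key)
        if len(labels) == 1:
            coefficients[v] = {labels[0]: 1.0}
            continue
        payoffs = candidate_payoffs(graph, profile, simcache, v)
        raw = {lab: payoffs.get(lab, 0.0) for lab in labels}
        total = sum(raw.values())
        if total <= 0.0:  # degenerate: no neighbor shares any label
            coefficients[v] = {lab: 1.0 / len(labels) for lab in labels}
        else:
            # retained labels must keep a strictly positive coefficient
            floor = 1e-9 * max(raw.values())
            raw = {lab: max(p, floor) for lab, p in raw.items()}
            total = sum(raw.values())
            coefficients[v] = {lab: p / total for lab, p in raw.items()}
    return Cover(cover.communities, coefficients), coefficients


def detect_communities(graph: Graph,
                       config: DetectionConfig = DetectionConfig()):
    """Full two-phase detection: returns (cover, coefficients, trace)."""
    from .phase_one import run_phase_one
    partition, trace = run_phase_one(graph, config)
    cover, coefficients = run_phase_two(graph, partition, config)
    return cover, coefficients, trace
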