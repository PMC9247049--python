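"""Planted-community benchmark graphs with controllable overlap.

The generator follows the standard planted-partition recipe with power-law
degree and community-size distributions (the LFR parameter vocabulary):

* node degrees ~ truncated power law with exponent tau1, lower cutoff
  solved so the sample mean hits the requested k_mean;
* community sizes ~ truncated power law with exponent tau2 on
  [c_min, c_max], drawn until they cover every membership slot;
* a fraction ``on`` of nodes is overlapping, holding ``om`` memberships
  each, the rest one;
* each node spends (1 - mu) of its degree on edges inside its own
  communities (split evenly across memberships) and mu on edges leaving
  them, wired configuration-model style with collision rewiring.

The mixing parameter mu is therefore the expected fraction of a node's
edges that leave all of its communities.  Everything is driven by one
seeded NumPy generator, so identical specs give identical graphs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Set, Tuple

import numpy as np

from .graph import Cover, Graph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of a planted overlapping-community benchmark."""

    n: int = 1000
    k_mean: float = 10.0
    k_max: int = 50
    mu: float = 0.1
    tau1: float = 2.0
    tau2: float = 1.0
    c_min: int = 10
    c_max: int = 50
    on: float = 0.0       # fraction of overlapping nodes
    om: int = 2           # memberships per overlapping node
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.mu < 1:
            raise ValueError("mu must lie in [0, 1)")
        if not 0 <= self.on <= 1:
            raise ValueError("on must lie in [0, 1]")
        if self.on > 0 and self.om < 2:
            raise ValueError("om must be >= 2 when overlap is requested")
        if not 3 <= self.c_min <= self.c_max <= self.n:
            raise ValueError("need 3 <= c_min <= c_max <= n")
        if self.k_max >= self.n:
            raise ValueError("k_max must be below n")
        if (1 - self.mu) * self.k_max > self.c_max - 1:
            raise ValueError(
                "infeasible: a k_max-degree node needs internal degree "
                f"{(1 - self.mu) * self.k_max:.0f} but communities hold at "
                f"most {self.c_max - 1} partners")
        if (1 - self.mu) * self.k_mean / self.om > self.c_min - 1:
            raise ValueError(
                "infeasible: average internal degree per membership exceeds "
                "the smallest allowed community")


# ---------------------------------------------------------------------------
# Power-law sampling
# ---------------------------------------------------------------------------

def _power_law_pmf(k_min: int, k_max: int, tau: float) -> np.ndarray:
    ks = np.arange(k_min, k_max + 1, dtype=float)
    w = ks ** (-tau)
    return w / w.sum()


def _degree_pmf(k_mean: float, k_max: int, tau: float) -> Tuple[int, np.ndarray]:
    """Discrete truncated power-law pmf on [k_min, k_max] whose mean equals
    k_mean, mixing the two adjacent integer lower cutoffs."""
    means = {}
    for k_min in range(1, k_max):
        pmf = _power_law_pmf(k_min, k_max, tau)
        means[k_min] = float(np.arange(k_min, k_max + 1) @ pmf)
        if means[k_min] >= k_mean:
            break
    lo = max((k for k, m in means.items() if m <= k_mean), default=None)
    hi = min((k for k, m in means.items() if m >= k_mean), default=None)
    if hi is None:
        raise ValueError(f"cannot reach mean degree {k_mean} with k_max {k_max}")
    if lo is None or lo == hi:
        return hi, _power_law_pmf(hi, k_max, tau)
    q = (means[hi] - k_mean) / (means[hi] - means[lo])  # weight on lo
    pmf = np.zeros(k_max - lo + 1)
    pmf[: k_max - lo + 1] += q * _power_law_pmf(lo, k_max, tau)
    pmf[hi - lo:] += (1 - q) * _power_law_pmf(hi, k_max, tau)
    return lo, pmf / pmf.sum()


def _sample_degrees(spec: BenchmarkSpec, rng: np.random.Generator) -> np.ndarray:
    k_min, pmf = _degree_pmf(spec.k_mean, spec.k_max, spec.tau1)
    ks = np.arange(k_min, spec.k_max + 1)
    degrees = rng.choice(ks, size=spec.n, p=pmf)
    return degrees.astype(int)


def _sample_sizes(spec: BenchmarkSpec, slots: int, min_largest: int,
                  rng: np.random.Generator) -> List[int]:
    """Community sizes summing exactly to the number of membership slots.

    ``min_largest`` guarantees one community can host the highest-degree
    node's internal neighbors.
    """
    pmf = _power_law_pmf(spec.c_min, spec.c_max, spec.tau2)
    sizes_range = np.arange(spec.c_min, spec.c_max + 1)
    sizes: List[int] = []
    total = 0
    while total < slots:
        s = int(rng.choice(sizes_range, p=pmf))
        sizes.append(s)
        total += s
    if max(sizes) < min_largest:
        i = sizes.index(max(sizes))
        total += min_largest - sizes[i]
        sizes[i] = min_largest
    big = sizes.index(max(sizes))  # shielded from trimming below min_largest
    floors = [min_largest if i == big else spec.c_min
              for i in range(len(sizes))]
    # trim the excess, largest communities first, never below each floor
    excess = total - slots
    while excess > 0:
        order = sorted(range(len(sizes)), key=lambda i: -sizes[i])
        moved = False
        for i in order:
            if excess == 0:
                break
            take = min(sizes[i] - floors[i], excess)
            if take > 0:
                sizes[i] -= take
                excess -= take
                moved = True
        if not moved:  # all at their floor: drop one minimal community
            j = max((i for i in range(len(sizes)) if i != big),
                    default=None)
            if j is None:
                raise ValueError("community-size bounds leave no feasible "
                                 "size sequence")
            excess -= sizes.pop(j)
            floors.pop(j)
            big = sizes.index(max(sizes))
            if excess < 0:  # overshot: grow communities back up
                for i in range(len(sizes)):
                    give = min(spec.c_max - sizes[i], -excess)
                    sizes[i] += give
                    excess += give
                    if excess == 0:
                        break
                if excess < 0:
                    raise ValueError("community-size bounds leave no "
                                     "feasible size sequence")
    return sizes


# ---------------------------------------------------------------------------
# Membership assignment
# ---------------------------------------------------------------------------

def _assign_memberships(spec: BenchmarkSpec, degrees: np.ndarray,
                        rng: np.random.Generator) -> Tuple[List[Set[int]], List[List[int]]]:
    """Place every membership slot in a community.

    Returns (memberships per node, member list per community).  A node fits
    a community only if its per-membership internal degree fits inside it;
    blocked placements evict a random lighter member (bounded retries).
    """
    n = spec.n
    n_over = int(round(spec.on * n))
    overlapping = set(rng.choice(n, size=n_over, replace=False).tolist())
    n_memb = np.array([spec.om if v in overlapping else 1 for v in range(n)])
    slots = int(n_memb.sum())
    int_need = np.ceil((1 - spec.mu) * degrees / n_memb).astype(int)
    sizes = _sample_sizes(spec, slots, int(int_need.max()) + 1, rng)
    n_comm = len(sizes)

    members: List[Set[int]] = [set() for _ in range(n_comm)]
    capacity = list(sizes)
    # heaviest requirements first so big nodes land in big communities
    order = sorted(range(n), key=lambda v: (-int_need[v], v))
    placement: Dict[int, Set[int]] = {v: set() for v in range(n)}
    queue: List[int] = []
    for v in order:
        queue.extend([v] * n_memb[v])
    attempts = 0
    max_attempts = 200 * slots
    idx = 0
    while idx < len(queue):
        v = queue[idx]
        feasible = [c for c in range(n_comm)
                    if capacity[c] > 0 and c not in placement[v]
                    and sizes[c] - 1 >= int_need[v]]
        if feasible:
            c = int(rng.choice(feasible))
            members[c].add(v)
            placement[v].add(c)
            capacity[c] -= 1
            idx += 1
            continue
        # evict a random member of a random admissible full community
        admissible = [c for c in range(n_comm)
                      if c not in placement[v] and sizes[c] - 1 >= int_need[v]]
        if not admissible:
            raise ValueError(
                f"infeasible: node of degree {int(degrees[v])} with "
                f"{int(n_memb[v])} membership(s) fits no community size")
        c = int(rng.choice(admissible))
        evictable = [u for u in members[c] if int_need[u] <= int_need[v]]
        u = int(rng.choice(evictable if evictable else list(members[c])))
        members[c].remove(u)
        placement[u].remove(c)
        members[c].add(v)
        placement[v].add(c)
        queue.append(u)
        idx += 1
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("membership assignment did not converge; "
                             "the spec is too tight")
    return [placement[v] for v in range(n)], [sorted(m) for m in members]


# ---------------------------------------------------------------------------
# Stub wiring
# ---------------------------------------------------------------------------

def _pair_stubs(stubs: List[int], rng: np.random.Generator, valid,
                register, unregister, pool_edges: List[Tuple[int, int]],
                max_rounds: int = 100) -> int:
    """Randomly pair stubs subject to ``valid``; returns dropped stub count.

    Stalled leftovers are consumed by degree-preserving double edge swaps
    against ``pool_edges`` (the edges already wired from this pool): break a
    random (u, v) and wire (a, u), (b, v) instead, keeping every degree.
    """

    def wire(a: int, b: int) -> None:
        register(a, b)
        pool_edges.append((a, b))

    pool = list(stubs)
    for _ in range(max_rounds):
        if len(pool) < 2:
            break
        rng.shuffle(pool)
        leftover: List[int] = []
        progressed = False
        for a, b in zip(pool[0::2], pool[1::2]):
            if valid(a, b):
                wire(a, b)
                progressed = True
            else:
                leftover.extend((a, b))
        if len(pool) % 2:
            leftover.append(pool[-1])
        pool = leftover
        if not progressed:
            break
    # double-swap repair for stubborn stubs
    dropped = 0
    while len(pool) >= 2:
        a, b = pool[-2], pool[-1]
        done = False
        if pool_edges:
            for _ in range(100):
                k = int(rng.integers(len(pool_edges)))
                u, v = pool_edges[k]
                for x, y in ((u, v), (v, u)):
                    if (valid(a, x) and valid(b, y) and {a, b} != {x, y}
                            and a != y and b != x):
                        unregister(u, v)
                        pool_edges[k] = pool_edges[-1]
                        pool_edges.pop()
                        wire(a, x)
                        wire(b, y)
                        done = True
                        break
                if done:
                    break
        del pool[-2:]
        if not done:
            dropped += 2
    return dropped + len(pool)


def generate_benchmark(spec: BenchmarkSpec) -> Tuple[Graph, Cover]:
    """Generate a benchmark graph and its planted ground-truth cover.

    Nodes are labeled 1..n.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    degrees = _sample_degrees(spec, rng)
    memberships, members = _assign_memberships(spec, degrees, rng)
    n_comm = len(members)

    # stochastic rounding keeps E[k_int] = (1 - mu) k even when mu * k < 1
    target = (1 - spec.mu) * degrees
    k_int = np.floor(target).astype(int)
    k_int += (rng.random(spec.n) < target - np.floor(target)).astype(int)
    k_int = np.minimum(k_int, degrees)
    adj: Dict[int, Set[int]] = {v: set() for v in range(spec.n)}

    def register(a: int, b: int) -> None:
        adj[a].add(b)
        adj[b].add(a)

    def unregister(a: int, b: int) -> None:
        adj[a].discard(b)
        adj[b].discard(a)

    def simple(a: int, b: int) -> bool:
        return a != b and b not in adj[a]

    # internal stubs, community by community
    comm_stubs: List[List[int]] = [[] for _ in range(n_comm)]
    for v in range(spec.n):
        ms = sorted(memberships[v])
        base, extra = divmod(int(k_int[v]), len(ms))
        picks = rng.permutation(len(ms))[:extra]
        for slot, c in enumerate(ms):
            d = base + (1 if slot in picks else 0)
            comm_stubs[c].extend([v] * d)
    dropped = 0
    for c in range(n_comm):
        stubs = comm_stubs[c]
        if len(stubs) % 2:
            stubs = stubs[:-1]
            dropped += 1
        dropped += _pair_stubs(stubs, rng, simple, register, unregister, [])

    # external stubs across communities
    def external_ok(a: int, b: int) -> bool:
        return simple(a, b) and not (memberships[a] & memberships[b])

    ext: List[int] = []
    for v in range(spec.n):
        ext.extend([v] * int(degrees[v] - k_int[v]))
    if len(ext) % 2:
        ext = ext[:-1]
        dropped += 1
    dropped += _pair_stubs(ext, rng, external_ok, register, unregister, [])
    if dropped:
        logger.warning("dropped %d unpaired/colliding stub(s)", dropped)

    graph = Graph(((u + 1, v + 1) for u in adj for v in adj[u] if u < v),
                  nodes=range(1, spec.n + 1))
    cover = Cover({c + 1: frozenset(v + 1 for v in members[c])
                   for c in range(n_comm)})
    return graph, cover


def realized_mixing(graph: Graph, cover: Cover) -> float:
    """Mean over nodes of the fraction of incident edges leaving all of the
    node's communities (the measured mixing parameter)."""
    membership = {v: set(ms) for v, ms in cover.membership_map().items()}
    fractions = []
    for v in graph:
        k = graph.degree(v)
        if k == 0:
            continue
        ext = sum(1 for u in graph.neighbors(v)
                  if not membership[v] & membership[u])
        fractions.append(ext / k)
    return float(np.mean(fractions)) if fractions else 0.0


# ---------------------------------------------------------------------------
# Small deterministic fixtures
# ---------------------------------------------------------------------------

def planted_fixture(kind: str, *sizes: int) -> Tuple[Graph, Cover]:
    """Deterministic toy graphs with known ground truth.

    ``two_cliques(a, b)``: two cliques joined by a single bridge edge;
    ``barbell_bridge(a, b, t)``: two cliques plus one designated bridge
    node with t edges into each (ground truth places it in both);
    ``ring_of_cliques(k, s)``: k cliques of size s in a ring.
    """
    if any(s < 2 for s in sizes) or (kind != "barbell_bridge" and
                                     any(s < 3 for s in sizes)):
        raise ValueError("fixture sizes too small")
    if kind == "two_cliques":
        a, b = sizes
        edges = _clique(range(1, a + 1)) + _clique(range(a + 1, a + b + 1))
        edges.append((a, a + 1))
        cover = Cover({1: frozenset(range(1, a + 1)),
                       2: frozenset(range(a + 1, a + b + 1))})
        return Graph(edges), cover
    if kind == "barbell_bridge":
        a, b, t = sizes
        if t > min(a, b):
            raise ValueError("bridge degree exceeds clique size")
        bridge = a + b + 1
        edges = _clique(range(1, a + 1)) + _clique(range(a + 1, a + b + 1))
        edges += [(bridge, v) for v in range(1, t + 1)]
        edges += [(bridge, v) for v in range(a + 1, a + t + 1)]
        cover = Cover({1: frozenset(range(1, a + 1)) | {bridge},
                       2: frozenset(range(a + 1, a + b + 1)) | {bridge}})
        return Graph(edges), cover
    if kind == "ring_of_cliques":
        k, s = sizes
        if k < 3:
            raise ValueError("ring needs at least 3 cliques")
        edges = []
        comms = {}
        for i in range(k):
            block = range(i * s + 1, (i + 1) * s + 1)
            edges += _clique(block)
            comms[i + 1] = frozenset(block)
            edges.append((i * s + 1, ((i + 1) % k) * s + 2))
        return Graph(edges), Cover(comms)
    raise ValueError(f"unknown fixture kind {kind!r}")


def _clique(nodes) -> List[Tuple[int, int]]:
    nodes = list(nodes)
    return [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
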