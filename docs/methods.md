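# Methods

## Model

Community detection is cast as a non-cooperative game on an undirected
simple graph G = (V, E). Each node i is a selfish agent whose strategy
s_i is a set of community labels; the strategy profile is
S = (s_1, …, s_n). Agent i's utility is

    U(S_-i, s_i) = Σ_{j ∈ Γ_i} (1 + sim_ij) · |s_i ∩ s_j| / sqrt(|s_j|)

where Γ_i is i's (open) neighborhood and sim_ij is a structural
similarity index of the adjacent pair. The sum runs over neighbors only:
agents interact locally, which is also what makes one sweep cost
O(Σ_i k_i) = O(m). An agent is rewarded for sharing labels with its
neighbors, more strongly with structurally similar ones, and a neighbor
spread across many communities contributes less through the
1/sqrt(|s_j|) attenuation.

Five similarity indices are available, all over open neighborhoods
(a node is never its own neighbor): Jaccard (JC), Salton/cosine (SI),
Sorensen (SO), hub-promoted (HP = |Γ_i ∩ Γ_j| / min(k_i, k_j)) and
hub-depressed (HD). Any vanishing denominator (an isolated endpoint)
gives similarity 0. HP is the default; the method's output depends only
weakly on the choice. Whether the endpoints themselves should count in
the intersection is a genuine ambiguity; the open-neighborhood
convention was chosen because it matches the standard definitions of
these indices in the link-prediction literature.

### Phase one — best-response label switching

Every node starts in a singleton community labeled by its own
identifier. Sweeps then visit all nodes in descending-degree order (ties
by node identifier) and each node immediately adopts the best-response
label among the labels of its neighborhood plus its own (strategies are
single labels in this phase, so |s_i ∩ s_j|/|s_j| is 0 or 1). Ties are
broken by retaining the current label when it attains the maximum
(preventing two-cycles), otherwise by the smallest label under a fixed
total order. The dynamics contain no randomness, so runs are exactly
reproducible.

The sweep direction is a design choice the model itself does not fix:
descending degree lets hubs consolidate labels early. On the karate
fixture descending order recovers the two-faction structure while
ascending order fragments one faction into two, so descending is the
default and the documented policy.

**Stop criterion.** An agent is *fixed* in a sweep when its adopted label
equals its label at the end of the previous sweep (the minimal, local
definition). With n_fixed agents fixed after the previous sweep, the run
stops as soon as the increase of the fixed count is at most
Δ_stop = ε · n_fixed (never before any agent is fixed). The slack ε
(default 0.01) trades accuracy for time on graphs where a few agents
oscillate indefinitely. ε = 0 is treated as a request for full
quiescence: the loop then stops only when a sweep makes no switch at
all. Applying the slackless formula literally would also stop on a
plateau of n_fixed while agents still switch, and the resulting labeling
need not be stable; at quiescence, by contrast, the labeling is
Nash-stable — no node can strictly improve its utility by any
single-label switch (the test suite verifies this by brute force on
random graphs). A safety cap of 100 sweeps guards against permanent
oscillation; reaching it is logged, not an error.

### Phase two — per-agent RMS thresholds for overlap

Phase one yields a partition. For each node, phase two evaluates the
utility of every community label present in its neighborhood (plus its
own), normalizes the payoffs by the maximum, and computes the node's
personal threshold: the root mean square of its normalized payoffs.
Every label whose normalized payoff is ≥ the threshold is added to the
node's strategy. The comparison is inclusive by design: the maximizing
label (normalized payoff 1) always survives, and a node pulled exactly
evenly by two communities (both normalized payoffs 1, threshold 1)
joins both — the desired behaviour for symmetric bridges. Labels are
only ever added, never removed, so the phase-one community of every node
is contained in its final strategy.

A pass is synchronous (all agents expand against the frozen pre-pass
cover), making the result order-independent. The pass is repeated twice
by default: in the second pass, neighbors that already hold several
labels contribute attenuated payoffs through 1/sqrt(|s_j|), which lets
chains of adjacent overlapping nodes be discovered. The RMS is taken
over all candidate labels including the agent's own — restricting it to
foreign labels is the other defensible reading, but including the own
label (whose normalized payoff is usually 1) gives a slightly stricter
threshold and was fixed once here.

Fuzzy output: each node's final labels receive coefficients equal to its
raw utilities renormalized to sum to 1 (a single-label node gets 1). A
retained label with zero raw payoff — possible only in degenerate
configurations — is floored at 1e-9 of the maximum before normalization
so coefficients stay strictly positive.

## Metrics

**Overlapping modularity Q_ov.** Belonging coefficients α_ic ∈ [0, 1]
(rows summing to 1; crisp covers get α_ic = 1/|s_i|) are passed through
the logistic transfer F(α_ic, α_jc) = σ(f(α_ic)) σ(f(α_jc)) with
f(x) = 2px − p and sharpness p = 30, and

    Q_ov = (1/2m) Σ_c [ Σ_{ij} F(α_ic, α_jc) A_ij
                        − (Σ_i ℓ_ic k_i · mean_j(ℓ_jc))² / 2m ]

with ℓ_ic = σ(f(α_ic)). Two numerical readings were fixed here. First,
each logistic factor is σ(f(α)) = 1/(1 + e^{−f(α)}): the opposite sign
makes F ≈ 1 when *neither* node belongs to the community, i.e. an
inverted membership weight (that variant is retained behind
`QovParams(printed_sign=True)` for comparison; with exactly two crisp
communities the two conventions coincide by complement symmetry).
Second, the null term includes the i = j pair, exactly as classical
modularity pairs a node's stubs with themselves; with this convention a
single all-inclusive crisp community has Q_ov = 0 to machine precision,
which is the natural degeneracy anchor (excluding self-pairs would leave
a spurious + Σk²/4m² ≈ 0.03 on typical test graphs). Note the null
normalization averages the transferred membership over all of V, so
Q_ov values are not numerically comparable to Newman modularity even for
partitions — only Q_ov-to-Q_ov comparisons are meaningful.

**Overlapping NMI.** Each community is a binary membership variable over
the nodes. For community X_k of one cover, H(X_k|Y) is the minimum
conditional entropy over the other cover's communities, restricted to
pairs whose matched cells dominate (h(P11) + h(P00) ≥ h(P10) + h(P01));
unmatched communities fall back to their unconditional entropy. With
H(X) = Σ_k H(X_k) and I = ½[(H(X) − H(X|Y)) + (H(Y) − H(Y|X))], the
reported score is I / max(H(X), H(Y)). The max-normalization (rather
than per-community normalization) is used because it gives the two
anchor identities exactly: NMI(X, X) = 1 and NMI = 0 between the
all-singletons and all-in-one covers, which per-community normalization
violates (it yields ½ on the latter pair). The implementation is
cross-checked in the tests against an independent brute-force evaluation
of the same defining equations over indicator matrices.

**AvgF1.** ½ [mean over communities a of max_b F1(a, b) + mean over b of
max_a F1(b, a)], with F1 the harmonic mean of set precision and recall.

**Cover statistics.** On = fraction of nodes with ≥ 2 memberships,
mean Om over overlapping nodes, community count and size histogram.

## Benchmark generator

The generator emulates the standard planted-partition family with
power-law degrees and community sizes (the LFR parameter vocabulary):
n, mean degree k̄, max degree k_max, mixing μ (a node spends (1 − μ) of
its degree inside its communities), exponents τ1 (degrees) and τ2
(sizes), size bounds [c_min, c_max], overlap fraction On and membership
count Om. Defaults (n = 1000, k̄ = 10, k_max = 50, μ = 0.1, τ1 = 2,
τ2 = 1, sizes 10–50, Om = 2) are the desk-scale study conditions used
throughout the tests.

Implementation choices:

* degrees are drawn by inverse-CDF from a discrete truncated power law;
  the lower cutoff is solved by mixing the two adjacent integer cutoffs
  so the expected mean equals k̄ exactly;
* community sizes are drawn from a truncated power law until they cover
  all membership slots, then trimmed deterministically to the exact slot
  count (one community is guaranteed large enough to host the
  highest-degree node's internal neighbors);
* memberships are assigned heaviest-requirement-first with random
  placement and bounded eviction, honoring a per-membership internal
  degree fit (a node's (1 − μ)k/Om internal partners must fit in the
  community);
* internal degree is stochastically rounded so E[k_int] = (1 − μ)k even
  when μk < 1 (deterministic rounding would bias realized mixing at
  small μ);
* stubs are wired configuration-model style per community (internal) and
  globally across communities (external, endpoints must share no
  community), with stalled leftovers consumed by degree-preserving
  double edge swaps; the few genuinely unplaceable stubs are dropped
  with a logged warning (typically < 3% of stubs at the defaults).

Exact equivalence with the original LFR software is a non-goal; the
contract is parameter semantics within tolerances (measured On within
±0.02, realized μ within ±0.03, mean degree within ~10%), seeded
determinism, and graph-invariant outputs. Generated graphs share LFR's
known departures from real networks — near-zero degree correlation and
low transitivity — so recovery results on them say nothing about, e.g.,
heavy triangle structure.

Three deterministic toy fixtures (`two_cliques`, `barbell_bridge`,
`ring_of_cliques`) provide hand-checkable ground truth for unit tests;
the barbell bridge node, with equal edges into both cliques, is the
canonical symmetric overlap case (coefficients 0.5/0.5).

## What the tests show — and what they do not

The acceptance-level checks run at desk scale: karate (n = 34),
random graphs up to n = 60 for the brute-force Nash check, and planted
benchmarks at n = 1000–4000 with k̄ = 10 and μ = 0.1. These sizes were
chosen so the full suite runs in seconds while still exercising the
size-scaling claim (sweep counts at n = 1000 vs 4000). Passing them
shows the dynamics converge, are deterministic and Nash-stable, and
recover low-mixing planted structure with NMI ≳ 0.95; it does not show
performance at high mixing (μ ≳ 0.5), on networks with strong degree
correlations, or at millions of nodes.

On the karate club, one caveat is structural: under the utility above,
node 9's payoff toward the administrator faction strictly dominates its
payoff toward the instructor faction for every similarity metric
(≈ 4.5 vs ≈ 2.6 with HP), so no stable state of this game places node 9
with the instructor — yet that is where Zachary's observed split puts
him (the one individual whose actual choice, famously, contradicted the
network structure). The detected cover therefore matches the observed
two-faction split on 33 of 34 nodes, with node 10 — whose only
neighbors sit one in each faction — correctly flagged as the sole
overlapping node with an even 0.5/0.5 membership.

## Known limitations

* Unweighted, undirected graphs only.
* Phase two only adds labels; a community spuriously merged in phase one
  cannot be split later.
* The ε-slackened stop rule can freeze a small fraction of oscillating
  agents in an arbitrary phase of their cycle; their final labels are
  deterministic but not payoff-maximal.
* Q_ov with p = 30 saturates for coefficients outside roughly
  [0.37, 0.63]; covers differing only in strongly-held memberships are
  not distinguished.
* The benchmark generator drops a small number of unplaceable stubs, so
  realized degrees are a slight underestimate of the drawn sequence.
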