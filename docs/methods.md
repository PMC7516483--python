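# Methods

## The score

`eminet` ranks the nodes of a complex network — a protein-interaction map, a
flight network, a friendship graph — by how much *diverse, non-redundant*
connectivity surrounds them. The intuition: a node matters when its
neighborhood is both well connected and evenly so (no single neighbor
dominates), but two adjacent nodes that share most of their neighbors
largely duplicate each other's reach and should not both be scored as if
their influence were independent.

For a directed, weighted network `G = (V, E, W)` the overall importance of
node *i* is

```
K_i = S_i + I_i + MI_i
```

with three components, all using base-10 logarithms by default:

**Structural entropy** `S_i = S_i_in + S_i_out`. Let `N_i` be the neighbor
set of *i* (union of in- and out-neighbors). `S_i_in` is the Shannon entropy
of the distribution obtained by normalising the in-degrees of the members of
`N_i`; `S_i_out` the same over their out-degrees. A degree of 0 contributes
a `0·log 0 = 0` term — this convention is load-bearing: a neighbor with
out-degree 0 must appear as a harmless zero term, not as an error. For
undirected networks a single entropy over the neighbor degrees is used.

**Interactive entropy** `I_i` repeats the construction with each neighbor's
inbound/outbound *weight sums* (strengths) in place of degree counts. It is
only defined for weighted networks; on an unweighted network it is skipped
and `K_i = S_i + MI_i`. With all weights equal to 1 it coincides exactly
with `S_i`, a consistency property the tests check.

**Mutual power** `MI_i ≤ 0`. For each neighbor *j*, with `N_ij = N_i ∩ N_j`
the common-neighbor set and `F` the size function,

```
MI_i = Σ_j  F(N_ij)/(F(N_i)+F(N_j)) · log[(F(N_i)+F(N_j)−F(N_ij)) / (F(N_i)+F(N_j))]
```

Every term is ≤ 0, zero exactly when *i* and *j* share no neighbor, so
`MI_i = 0` iff *i* shares no neighbor with any of its neighbors. Two
readings of the joint set `N(i,j)` are conceivable; we take
`F(N(i,j)) = F(N_i) + F(N_j)` (the multiset combination of the two
neighborhoods). Only this reading reproduces the published worked-example
values (MI_a = −0.03876, MI_b = MI_c = −0.05062 on the four-node fixture).
Similarly, the nested sum over the two random events collapses to one term
per neighbor pair; whether common-neighbor counts > 1 should contribute
repeated terms cannot be decided from the worked example (all its counts are
0 or 1, where the readings coincide). We default to the single-term reading,
which keeps each pair's joint mass a probability, and expose the repeated
reading as the expert option `EmiConfig(mi_pair_multiplicity=True)`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `log_base` | 10 | base of every logarithm; rescales all entropies by a constant factor, leaving rankings unchanged |
| `compat_single_neighbor` | off | include a node's own degrees/strengths in the entropy multiset when it has exactly one neighbor (see below) |
| `weight_shift` | on | shift edge weights by `w − w_min + 1` at load when any weight ≤ 0 |
| `mi_pair_multiplicity` | off | weight each mutual-power pair term by the common-neighbor count |

**The single-neighbor convention.** Strict evaluation of the entropy
formulas gives 0 for a degree-one node: its neighbor multiset has one
element and carries no uncertainty. The published worked-example table
nevertheless reports nonzero entropies for its degree-one node; those
values are reproduced exactly by augmenting the one-element multiset with
the node's own degrees/weight sums. Both behaviors are kept: strict is the
default (it follows the formulas), compat reproduces the table verbatim.
We do not guess which the original authors regard as canonical.

**Negative weights.** The entropy construction needs non-negative values
that normalise to a probability distribution. Signed affinity scales (e.g.
friendship ratings from −1 to +3) are shifted at load time so the smallest
weight becomes 1; the switch is exposed because the right treatment is
application-dependent and no canonical answer exists.

**Isolated nodes** score `K = 0` with a warning rather than raising, so
whole-network ranking never aborts.

## Baseline centralities

Degree (union-neighbor count), closeness (reciprocal farness over
*reachable* nodes only, 0 for a node that reaches nothing — the
least-surprising extension to disconnected graphs), k-shell (iterative
minimum-degree pruning; directed networks use total in+out degree),
betweenness (normalised by `(n−1)(n−2)`, halved for undirected), and
eigenvector centrality are standard and delegate to networkx or a small
power iteration; k-shell is cross-checked in the tests against an
independent brute-force pruning oracle. The simplified PageRank —
uniform start summing to 1, column-normalised transition update, dangling
mass redistributed uniformly, *no damping* by default — is implemented
directly since library PageRank always damps; a damping option (0.85) is
exposed. Shortest-path centralities read edge weight as length; because
many networks carry affinity weights, an inverse-weight option exists.

## Ranking evaluation

A ranking is an ordered partition of the nodes into tie groups. Scores are
grouped by rounding to `−log10(tol)` decimals (default tol `1e-10`):
deterministic and order-independent, unlike pairwise chaining. Two metrics:

* monotonicity `M(R) = (1 − Σ_r n_r(n_r−1)/(n(n−1)))²` with `n = |V|` and
  `n_r` the tie-group sizes — 1 when all ranks are distinct, 0 when all
  nodes tie. (With `n` read as the number of *ranks* the formula would
  violate both of those endpoint identities, so the node-count reading is
  the implemented one.)
* the rank-occupancy CCDF `(|V| − Σ_{i≤r} n_i)/|V|` — slowly decaying
  curves mean finely resolved rankings.

Top-k overlap between two rankings flattens tie groups with the
deterministic tie-break (descending score, then ascending node id).

## SI spreading

Seed sets are scored by a discrete-time susceptible–infected process: at
each synchronous step every infected node attempts each susceptible
out-neighbor once, succeeding with probability β (unweighted) or
`λ_ij = (w_ij / w_max)^α` (weighted; `w_max` the global maximum weight,
α > 0, default 1 since no canonical value exists). There is no recovery, so
the infected set grows monotonically and the mean final count over
Monte-Carlo repetitions (default 100) measures seed influence. Runs stop at
the step cap or when no susceptible node is adjacent to an infected one —
without the cap the process would never terminate on graphs the seeds
cannot fully reach. Every run draws from an independent `SeedSequence`
substream, so results are bit-reproducible, and `seed_set_experiment` gives
every compared method the identical substreams per (k, run) pair so
method comparisons are variance-paired.

## Synthetic generators; what the tests do and do not show

Star/path/cycle/complete families anchor closed-form checks (star center
`S = log10(k)`, complete-graph symmetry and `M(R) = 0`). Erdős–Rényi draws
with optional direction and integer weights (count-style weights, as in
flight networks) drive the property tests: entropy bounds
`0 ≤ S_in ≤ log10|N_v|`, `MI ≤ 0` with equality iff no shared neighbors,
`I = S` at unit weights, permutation equivariance, and oracle agreement.

The two-hub overlap family isolates the redundancy penalty. One subtlety
found while testing: with hub degree held fixed, swapping private leaves
(degree 1) for shared leaves (degree 2) changes the neighbor-degree
multiset, so structural entropy rises and the hub's K is *not* monotone in
the overlap — it peaks at intermediate sharing. The penalty claim is
therefore stated and tested at the two levels where it is exact: MI itself
is strictly decreasing in the shared count, and K is strictly decreasing
once the neighbors' degrees are equalised (a pendant on each private leaf).

These generators emulate edge-sampling randomness and count weights; they
do not reproduce the heavy-tailed degree distributions, clustering or
community structure of real networks, so passing property tests demonstrate
correctness of the formulas and invariances, not predictive performance on
any particular real dataset. Published large-network benchmark comparisons
require external dataset downloads and are intentionally out of scope; the
evaluation harness (`evaluate`, `simulate`) will reproduce them when a user
supplies the edge lists.

## Problem sizes

Randomised tests use graphs of 12–60 nodes and SI checks of 1000–2000
Monte-Carlo runs on ≤ 12-node families — sizes at which the independent
oracles (brute-force pruning, literal formula evaluation, binomial
expectations) are exact and fast. The acceptance script runs entirely on
the four-node fixture plus 10-node analytic rankings.

## Known limitations

* Stress, radiality, bridging, centroid, eccentricity and DMNC centralities
  are not reimplemented (no defining equations available to us); externally
  computed score files can be registered for comparison instead.
* No incremental recomputation after edge updates; scores are recomputed
  from scratch.
* The per-node computation visits each neighbor's full edge set, so dense
  graphs cost O(n·m) in the worst case; fine at the tested scales, not
  tuned for million-edge graphs.
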