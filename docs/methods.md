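# Methods

## Temporal model and windowing

The raw input is a stream of timestamped interaction events.  Analysis
operates on a sequence of snapshots `G_t = (V, E_t)` built with sliding
windows of duration `Δt` and step `s` (default `s = Δt/2`, i.e. 50%
overlap; the window-sensitivity sweep keeps that overlap ratio fixed
while rescaling `Δt`).  Windows are half-open `[start, start + Δt)`, so
an event on a boundary belongs to the next window only; with `s < Δt`
one event legitimately appears in several snapshots.  `V` is fixed as
the union of node identifiers over the whole horizon: a node inactive in
a window stays in `V` with degree zero, which keeps every
`|V|`-normalized quantity comparable across windows and across
disruption states.  Snapshots are simple and undirected — repeated
interactions within a window collapse to one edge, directed records are
symmetrized, self-loops are dropped (their count is logged).  Input
weights are parsed and retained on the event table but ignored by the
pipeline.

## Motifs, matching, and persistence

Cycle instances are simple cycles of length 3 to `max_len` (default 5)
enumerated per snapshot.  Identity for cross-window matching is the
sorted node set; distinct edge embeddings on one node set (possible once
chords exist) are grouped under one instance but each embedding is kept,
so the presence test stays edge-exact:

    φ(c, t) = 1  ⟺  some recorded embedding of c is ⊆ E_t
    τ(c)    = Σ_t φ(c, t) · Δt

φ is evaluated retroactively over *all* windows once an instance is
known, including windows before its first detection and embeddings
discovered later.  This is the executable reading of node-set matching
combined with containment-based existence: presence depends only on the
snapshot's edges, not on when the inventory first saw the motif.
Consequences worth knowing: τ > 0 for every record, τ is invariant to
window processing order, and adding edges can only increase τ.

2-paths (one center, two distinct neighbors) are the open-motif
comparison family, processed by the identical tracking pipeline.  By
default the closing edge between the endpoints may also be present:
requiring its absence would make φ non-monotone under edge addition and
no operational openness test is part of the model; `require_open=True`
provides the strict reading.

Within-window containment is the whole temporal-feasibility criterion:
no additional time ordering *inside* a window is checked, because
windows are the time resolution of the model.  Cross-window cycles whose
edges never co-occur in one window are out of scope.

## Hypernetwork and threshold selection

Motifs with `τ ≥ τ_min` become hyperedges weighted `w(e_c) = τ(c)`
(an optional length-normalized weighting exists but is off by default).
The co-participation adjacency `A_H(i,j)` sums the weights of hyperedges
containing both nodes; the diagonal is fixed at zero since
self-co-participation is meaningless.  Two exact identities are enforced
by tests on every instance: symmetry, and
`Σ_{i<j} A_H(i,j) = Σ_e w(e)·C(|e|,2)`.

`τ_min` is selected among percentiles {Q50, Q60, Q70, Q80, Q90} of the
empirical τ distribution (linear interpolation, so results are
bit-for-bit reproducible).  For each candidate, node scores are computed
on every trailing sub-horizon of `subwindow` consecutive windows
(default 5) and the stability score is the mean Spearman ρ between
consecutive rankings; candidates retaining fewer than `η` motifs
(default 10) are infeasible, and ties prefer the higher percentile — the
compactest representation.  An undefined ρ (constant ranking) counts as
0 toward the mean, a conservative choice that penalizes degenerate
candidates.  The stability metric defaults to TCN; TCR is available via
a flag.  If no candidate is feasible the selection raises with guidance
(lower `η`, or shrink `Δt` so persistence can accumulate) rather than
silently picking a degenerate threshold.

## Node metrics

`TCN_i(t₁,t₂)` sums the full-horizon τ of every cycle containing `i`
that is present in at least one window of `[t₁,t₂]`; the structural-role
weight is fixed at 1, so TCN is a persistence-weighted cycle count (a
role-weight hook exists in the interface).  Using the full-horizon τ
rather than an interval-truncated one is the reading consistent with the
worked five-node example, where τ accumulated over the whole horizon is
summed directly.  `TCR_i` divides by the interval's cumulative windowed
degree plus `ε = 1e-9` — far below any integer degree sum, so printed
two-decimal ratios are unaffected while isolated nodes map to 0 instead
of dividing by zero.  Conservation, `Σ_i TCN_i = Σ_c τ(c)·|c|`, holds
exactly and is tested on every random instance.  P2N/P2R credit all
three member nodes of a 2-path, mirroring "cycles containing node i";
center-only crediting is available (`credit="center"`).

Baselines are computed on the same snapshot sequence: betweenness and
k-core on the time-aggregated union graph, and a temporal betweenness
that counts minimum-hop earliest-arrival time-respecting paths (distinct
(edge, window-label) sequences; with one window it reduces exactly to
static betweenness).  The path counting is exhaustive and exponential in
the worst case — it is a desk-scale baseline for rank comparisons, not a
large-network tool.

## Reachability dialect and resilience measures

One reachability dialect is used everywhere: waiting at nodes is
allowed, any number of hops may be taken within a window, and latency is
counted in windows (`d(i,j) − t_s + 1`, with `d(i,i) = t_s`).  Waiting
makes reachability from window 1 subsume every later start, which keeps
TRR a single number.  Earliest arrivals are computed by expanding
per-source reachable sets through each window's connected components
(one pass per window suffices because components are maximal); the
implementation is cross-checked against an independent time-expanded
digraph oracle.

- Temporal efficiency `E` = mean over ordered pairs of inverse latency,
  with `1/∞ = 0`; `start_mode="first"` (default) uses `t_s = 1`,
  `"averaged"` averages over all start windows.  Absolute values are
  never compared across modes.
- `TRR` = fraction of ordered pairs with finite earliest arrival.
- `LTCC` = size of the largest *weakly* connected component of the
  reachability digraph (arc `i→j` iff `j` reachable from `i`); an
  edgeless network has LTCC = 1.

Node removal deletes all incident edges in every window but keeps the
node in `V` as an isolate, so the `|V|(|V|−1)` denominators are stable
pre/post.  Attack strategies: `targeted` removes the top
`round(budget·|V|)` nodes of a pre-computed score (ties broken by node
identifier; rankings are never recomputed after removals), `random`
draws uniformly under a seed (bitwise reproducible), and `hybrid` — a
named strategy without a fixed definition in the literature we follow —
removes the ceiling half of the budget targeted and the rest uniformly
from the remaining nodes; its composition is recorded in output
metadata.  Identical seed lists are reused across strategies so
comparisons are paired; strategy differences are tested with a one-sided
paired Wilcoxon signed-rank at significance 0.01.

Rank associations between scores and impacts use Spearman ρ with
average-rank ties (Kendall τ as the robustness check); identical vectors
short-circuit to exactly 1.0, and constant vectors return NaN with a
warning rather than a fabricated value.  Per-node impacts can come from
single-node removals (`single_node_impacts`) or small-group removals
(`run_attack`); both protocols are supported because either can be the
quantity of interest.

## Synthetic generator

The generator emulates the study conditions the pipeline is validated
under: *planted cycles* whose full edge sets reappear independently per
window with probability `p_on`; an independent per-window Erdős–Rényi
noise layer with per-pair probability `q` (the simplest null producing
transient closures for the τ_min filter to remove); optional *planted
persistent dyads*; and *hub* confounders — nodes excluded from all
planted cycles that receive a fixed number of uniformly random partners
per window, decoupling degree from persistent-cycle membership.  Planted
cycles may pairwise share at most one node by default; two simple cycles
sharing a single vertex cannot compose into a new simple cycle, so with
`q = 0` the inventory equals the planted set exactly.  τ/(T_w·Δt) of a
planted cycle is a binomial proportion estimating `p_on` (a planted
cycle can also be completed by noise, probability ~q per missing edge —
negligible at the defaults).  Everything is deterministic under the
seed and the ground truth is returned for recovery tests.

What the generator does *not* emulate: burstiness, circadian rhythms,
degree heterogeneity beyond the hub construct, or any statistical
fingerprint of real interaction data.  Passing tests therefore
demonstrate correctness of the machinery and recoverability under
controlled conditions, not performance guarantees on real data.

Two named study configurations ship with the package:

- `planted_triangles_config()` — parameter recovery: 3 disjoint
  triangles with `p_on = 0.9`, `q = 0.02`, 30 nodes, 40 unit windows.
  The recovery analysis selects τ_min with `η = 3`: only three
  persistent cycles exist by construction, so the default `η = 10`
  would reject every candidate by design.
- `hub_confounded_config()` — attack benchmark: 61 nodes, 40 windows; a
  chain of 27 always-on triangles (`p_on = 1`) spans the 55 core nodes
  and is the only reliable connectivity backbone; 6 hubs with 5 random
  partners per window dominate every degree ranking (degree sum ≈ 200
  vs ≈ 160 for the busiest backbone node) while `q = 0.002` keeps the
  background sparse.  The chain's shared nodes belong to two triangles
  each, so persistence-filtered TCN ranks them first; removing them
  severs the backbone, whereas removing hubs deletes shortcuts the
  backbone makes redundant.  This benchmark is *constructed* so that the
  cycle-anchor mechanism is true by design: it validates that the
  pipeline detects the mechanism where it exists, not that the mechanism
  exists in any particular real system.  The benchmark pipeline runs
  with `max_len = 3` — the planted structure is triangles, and bounding
  enumeration at 3 keeps the transient 4/5-cycle combinatorics of the
  hub layer out of the inventory.

## Problem sizes and defaults

| parameter | default | notes |
| --- | --- | --- |
| `Δt`, step | data units, `Δt/2` | windows half-open; step ≤ Δt enforced |
| `max_len` | 5 | cycle length bound; enumeration is exact but grows quickly with density |
| `ε` | 1e-9 | TCR/P2R denominator guard |
| `τ_min` percentiles | Q50…Q90 | linear interpolation |
| `η` | 10 | minimum retained motifs |
| `subwindow` | 5 windows | stability sub-horizon length |
| efficiency start mode | `first` | `averaged` available |
| budgets/seeds | caller-chosen | paired seeds across strategies |

Validation problem sizes: oracle equivalence on 50 random instances with
n ≤ 10 nodes and ≤ 5 windows (exhaustive oracles are exponential);
recovery over 50 generator seeds; attack ordering over 100 paired seeds
of the 61-node benchmark.  These sizes make the full suite run in a few
minutes on one core while keeping every check exact or
statistically well-powered.

## Known limitations

- Cycle identity is the node set; a node set whose embedding changes
  completely between windows still accrues τ.  Embedding-level identity
  would be stricter; the node-set convention is what the matching step
  defines and what the toy example exercises.
- No within-window time ordering is checked; Δt is the causal
  resolution.
- Exact cycle enumeration is exponential in dense snapshots; choose Δt
  so snapshots are sparse, or lower `max_len`.
- Temporal betweenness enumerates paths exhaustively and is unusable
  beyond small networks.
- τ values are comparable only within one dataset/windowing; use ranks
  across datasets.
- Absolute ΔE depends on the reachability dialect (waiting, per-window
  hops, start-mode); only comparisons under one dialect are meaningful.
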