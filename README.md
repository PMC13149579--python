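# cyclenet

Persistent-cycle hypernetworks for temporal-network resilience analysis.

Many networked systems — face-to-face contacts, flight movements, neural
activity, email, power grids, trade — are streams of time-stamped
interaction events.  Their resilience depends on *time-respecting*
connectivity: a disruption matters when it removes routes that can be
traversed in chronological order.  Cycles are the minimal closed
redundancy units of a graph (a cycle certifies a detour), but in a
temporal network a cycle seen in one snapshot may be a one-off
coincidence.  `cyclenet` separates durable closure from incidental
closure by tracking how often each cycle recurs across sliding windows,
and uses that persistence signal to rank nodes and predict where
targeted failures hurt most.

It is a library first (`import cyclenet`), with narrative scripts in
`examples/` and a thin `cyclenet` command-line wrapper.

## The model

Events are binned into windowed snapshots `G_t = (V, E_t)`, `t = 1..T_w`
(fixed node set, undirected simple edges, half-open windows, optional
overlap).  For every motif instance `c` — simple cycles up to a length
bound, and 2-paths as the open-motif comparison family — matched across
windows by its canonical node-set identity:

- presence: `φ(c, t) = 1 ⟺ c ⊆ G_t` (all edges of some recorded
  embedding present in window `t`);
- persistence: `τ(c) = Σ_t φ(c, t) · Δt`;
- hypernetwork: motifs with `τ(c) ≥ τ_min` become hyperedges `e_c`
  weighted `w(e_c) = τ(c)`, with co-participation adjacency
  `A_H(i,j) = Σ_{e ∋ i,j} w(e)`;
- node scores: `TCN_i(t₁,t₂) = Σ_{c ∋ i, active in [t₁,t₂]} τ(c)` and
  `TCR_i = TCN_i / (Σ_t k_i(t) + ε)`, where `k_i(t)` is the windowed
  degree — TCN measures absolute persistent-closure involvement, TCR
  how efficiently a node's activity converts into durable closure.
  P2N/P2R are the same scores computed from 2-paths.

The threshold `τ_min` is chosen from percentiles {Q50…Q90} of the
empirical τ distribution by maximizing adjacent-interval rank stability
(Spearman ρ) subject to retaining at least `η` motifs.

Resilience is evaluated with node-removal experiments: earliest-arrival
reachability (waiting allowed, unlimited hops per window) yields
temporal efficiency `E` (mean inverse arrival latency), the temporal
reachability ratio `TRR`, and the largest temporal component `LTCC`;
impact is the relative drop ΔE/ΔTRR/ΔLTCC under random, degree-based,
or cycle-metric-based removals at a given budget.

## Worked example

The built-in fixture has five nodes and three unit windows containing
two triangles, each present in two of the three windows:

```
$ python examples/01_toy_walkthrough.py
cycle persistence (delta_t = 1):
  nodes (1, 2, 3): phi = (1, 1, 0), tau = 2
  nodes (2, 3, 4): phi = (0, 1, 1), tau = 2

node scores:
   tcn   tcr  degree_sum
1  2.0  0.40         5.0
2  4.0  0.50         8.0
3  4.0  0.50         8.0
4  2.0  0.33         6.0
5  0.0  0.00         3.0

co-participation A_H(2,3) = 4.0
```

Nodes 2 and 3 belong to both persistent triangles (TCN = τ_A + τ_B = 4);
node 5 closes no cycle at all (TCN = 0) even though it is active in
every window.  The same pipeline runs from the shell:
`cyclenet toy`, or `cyclenet score --input events.tsv --delta-t 300`
for SocioPatterns-style data (`--dialect tij`).

The other examples show the full analyses on synthetic data with known
ground truth: `02_planted_recovery.py` (the percentile rule recovers
three planted triangles, τ_min = 35, from per-window noise),
`03_attack_experiment.py` (removing 10% of nodes by persistence-filtered
TCN degrades temporal efficiency more than degree-ranked or random
removals: mean ΔE 0.231 vs 0.189 / 0.191 over 10 paired seeds), and
`04_window_sensitivity.py` (TCN rankings stay rank-correlated ρ ≥ 0.84
across window-size multipliers 0.5–2).

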