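"""Targeted node removal: persistent-cycle anchors versus degree hubs.

Uses the hub-confounded benchmark: a chain of always-on triangles spans
the 55 core nodes (the connectivity backbone), while 6 hub nodes gather
the highest degrees from transient random partners.  Removing 10% of
nodes ranked by persistence-filtered TCN (a cycle-based attack, CBA)
severs the backbone; removing by degree (DBA) only deletes the hubs'
redundant shortcuts; random failure (RF) sits in between.  Impact is the
relative loss of temporal efficiency ΔE, plus reachability (ΔTRR) and
fragmentation (ΔLTCC).
"""

import numpy as np

from cyclenet import (
    attack_frame,
    generate,
    hub_confounded_config,
    participation_scores,
    run_attack,
    select_tau_min,
    track,
    window_degrees,
)

config = hub_confounded_config()
results = []
for seed in range(10):  # paired seeds across strategies
    snapshots, truth = generate(config, seed=seed)
    inventory = track(snapshots, family="cycles", max_len=3)
    tau_min = select_tau_min(inventory, snapshots, eta=10).tau_min
    tcn_scores = participation_scores(inventory, tau_min=tau_min)
    degree_scores = window_degrees(snapshots).sum(axis=1).astype(float)
    results += run_attack(snapshots, tcn_scores, "targeted",
                          budgets=[0.1], seeds=[seed], label="CBA(TCN)")
    results += run_attack(snapshots, degree_scores, "targeted",
                          budgets=[0.1], seeds=[seed], label="DBA")
    results += run_attack(snapshots, None, "random",
                          budgets=[0.1], seeds=[seed], label="RF")

df = attack_frame(results)
summary = df.groupby("strategy")[["dE", "dTRR", "dLTCC"]].agg(["mean", "std"])
print("mean impact of removing 10% of nodes (10 paired seeds):")
print(summary.round(3).to_string())
print("\nCBA removes the chain's shared nodes, so ΔE exceeds DBA "
      "even though the hubs have the largest degree sums.")
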