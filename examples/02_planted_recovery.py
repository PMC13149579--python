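"""Recovering planted persistent cycles from per-window noise.

Generates a 30-node, 40-window network with three disjoint triangles
that each reappear with probability 0.9, plus transient Erdős–Rényi
noise edges.  The percentile-stability rule then picks the persistence
threshold tau_min; if the filter works, the retained hyperedges are
exactly the planted triangles, and their weights estimate
p_on * T_w (here about 36 of 40 windows).
"""

from cyclenet import (
    build_hypernetwork,
    generate,
    planted_triangles_config,
    select_tau_min,
    track,
)

config = planted_triangles_config()  # 3 triangles, p_on=0.9, q=0.02
snapshots, truth = generate(config, seed=7)
print("planted:", [tuple(p["nodes"]) for p in truth["planted_cycles"]],
      "with p_on =", truth["planted_cycles"][0]["p_on"])

inventory = track(snapshots, family="cycles", max_len=3)
print(f"detected {len(inventory)} distinct triangles "
      f"(planted + one-off noise closures)")

selection = select_tau_min(inventory, snapshots, metric="tcn", eta=3)
print(f"\nselected tau_min = {selection.tau_min:g} "
      f"(Q{selection.percentile} of the tau distribution)")
print(selection.stats.to_string(index=False))

hn = build_hypernetwork(inventory, selection.tau_min)
print("\nretained hyperedges (weight = tau, in windows):")
print(hn.hyperedge_frame().to_string(index=False))
print("\nA noise triangle would need to recur ~36/40 windows to survive "
      "the filter; one-off closures are dropped.")
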