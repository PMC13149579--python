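"""How stable are TCN rankings when the window size changes?

Persistence depends on the windowing: too-small windows fragment cycles,
too-large windows aggregate everything.  This sweep rebuilds the whole
pipeline at window multipliers {0.5, 0.75, 1, 1.5, 2} of the base
duration (50% overlap throughout) and reports Spearman's rho between
each ranking and the baseline one.  The planted backbone keeps the
ranking stable; rho = 1 at multiplier 1 by construction.
"""

from cyclenet import (
    generate,
    planted_triangles_config,
    snapshots_to_events,
    window_sensitivity,
)

snapshots, _ = generate(planted_triangles_config(), seed=3)
events = snapshots_to_events(snapshots)

table = window_sensitivity(events, delta_t0=1.0, metric="tcn", max_len=3)
print(table.round(3).to_string(index=False))
print("\nrho near 1 across multipliers means the persistent-cycle ranking "
      "is not an artifact of the particular window size.")
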