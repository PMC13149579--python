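"""Synthetic temporal networks with planted persistent structure.

The generator emulates the study conditions of the analysis pipeline:
a set of *planted cycles* whose full edge sets reappear independently in
each window with probability ``p_on`` (the persistent backbone), an
Erdős–Rényi noise layer drawn independently per window with per-pair
probability ``q`` (transient edges and occasional one-off cycles), and
optional *hub* nodes that receive many random edges per window while
staying outside every planted cycle — an activity confounder that
decouples degree from persistent-cycle membership.  Optional planted
edges (persistent dyads) let experiments wire non-cycle structure such
as spokes.

Planted cycles may pairwise share at most one node by default: two
simple cycles sharing a single vertex cannot compose into a new simple
cycle, so with ``q = 0`` the motif inventory contains exactly the
planted cycles.  Everything is deterministic under the seed, and the
ground truth is returned alongside the data.

The module also ships a small hand-checkable fixture: five nodes, three
unit windows, two triangles that each persist for two windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .temporal import SnapshotSequence, undirected_edge

__all__ = [
    "PlantedCycle",
    "GeneratorConfig",
    "generate",
    "toy_fixture",
    "snapshots_to_events",
    "planted_triangles_config",
    "hub_confounded_config",
]


@dataclass(frozen=True)
class PlantedCycle:
    """A cycle whose full edge set appears in a window with prob. p_on."""

    nodes: tuple
    p_on: float = 1.0

    def __post_init__(self):
        if len(self.nodes) < 3:
            raise ValueError(f"planted cycle needs >= 3 nodes, got {self.nodes}")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"planted cycle repeats nodes: {self.nodes}")
        if not 0 <= self.p_on <= 1:
            raise ValueError(f"p_on must be in [0, 1], got {self.p_on}")

    @property
    def edges(self) -> frozenset:
        m = len(self.nodes)
        return frozenset(
            undirected_edge(self.nodes[i], self.nodes[(i + 1) % m]) for i in range(m)
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic temporal network.

    ``noise_q`` is the per-pair, per-window probability of a transient
    noise edge.  ``hubs`` lists node ids excluded from all planted
    cycles that additionally get ``hub_edges_per_window`` random
    partners (drawn from non-hub nodes) in every window.
    ``planted_edges`` are persistent dyads ``(u, v, p_on)``.  With
    ``allow_overlap=False`` (default) planted cycles must pairwise share
    at most one node, which guarantees no unplanted cycle can form from
    the backbone alone.
    """

    n_nodes: int
    n_windows: int
    planted: tuple = ()
    noise_q: float = 0.0
    hubs: tuple = ()
    hub_edges_per_window: int = 0
    planted_edges: tuple = ()
    delta_t: float = 1.0
    allow_overlap: bool = False

    def __post_init__(self):
        if self.n_nodes < 1 or self.n_windows < 1:
            raise ValueError("n_nodes and n_windows must be positive")
        if not 0 <= self.noise_q <= 1:
            raise ValueError("noise_q must be in [0, 1]")
        universe = set(range(self.n_nodes))
        for pc in self.planted:
            if not set(pc.nodes) <= universe:
                raise ValueError(f"planted cycle {pc.nodes} leaves node universe")
        hubs = set(self.hubs)
        if not hubs <= universe:
            raise ValueError("hub ids leave node universe")
        for pc in self.planted:
            if hubs & set(pc.nodes):
                raise ValueError("hubs must stay outside all planted cycles")
        if not self.allow_overlap:
            for a, b in combinations(self.planted, 2):
                shared = set(a.nodes) & set(b.nodes)
                if len(shared) > 1:
                    raise ValueError(
                        f"planted cycles {a.nodes} and {b.nodes} share {len(shared)} "
                        "nodes; overlapping backbones need allow_overlap=True"
                    )


def generate(config: GeneratorConfig, seed: int | None = None):
    """Draw one temporal network under the given study conditions.

    Returns ``(snapshots, ground_truth)`` where ``ground_truth`` records
    the planted cycles (with node sets and p_on), hubs, and noise level,
    ready to serialize as a JSON sidecar.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    nodes = tuple(range(config.n_nodes))
    pairs = list(combinations(nodes, 2))
    non_hub = [v for v in nodes if v not in set(config.hubs)]

    windows = []
    for _ in range(config.n_windows):
        edges = set()
        for pc in config.planted:
            if rng.random() < pc.p_on:
                edges |= pc.edges
        for u, v, p_on in config.planted_edges:
            if rng.random() < p_on:
                edges.add(undirected_edge(u, v))
        if config.noise_q > 0:
            mask = rng.random(len(pairs)) < config.noise_q
            edges.update(pairs[i] for i in np.nonzero(mask)[0])
        for hub in config.hubs:
            pool = [v for v in non_hub if v != hub]
            k = min(config.hub_edges_per_window, len(pool))
            if k > 0:
                partners = rng.choice(np.array(pool), size=k, replace=False)
                edges.update(undirected_edge(hub, int(v)) for v in partners)
        windows.append(frozenset(edges))

    snapshots = SnapshotSequence(
        nodes=nodes,
        edges=tuple(windows),
        delta_t=config.delta_t,
        window_starts=tuple(
            float(k) * config.delta_t for k in range(config.n_windows)
        ),
    )
    ground_truth = {
        "planted_cycles": [
            {"nodes": list(pc.nodes), "p_on": pc.p_on} for pc in config.planted
        ],
        "planted_edges": [list(e) for e in config.planted_edges],
        "hubs": list(config.hubs),
        "hub_edges_per_window": config.hub_edges_per_window,
        "noise_q": config.noise_q,
        "n_nodes": config.n_nodes,
        "n_windows": config.n_windows,
        "delta_t": config.delta_t,
        "seed": seed,
    }
    return snapshots, ground_truth


def toy_fixture() -> SnapshotSequence:
    """Five nodes, three unit windows, two two-window triangles.

    Window edge sets:
        t=1: {12, 23, 31, 34, 45}
        t=2: {12, 23, 31, 24, 34, 25}
        t=3: {23, 34, 42, 15}

    The triangle on {1,2,3} is present in windows 1-2, the triangle on
    {2,3,4} in windows 2-3, so both have tau = 2 with delta_t = 1.
    """
    windows = (
        frozenset({(1, 2), (2, 3), (1, 3), (3, 4), (4, 5)}),
        frozenset({(1, 2), (2, 3), (1, 3), (2, 4), (3, 4), (2, 5)}),
        frozenset({(2, 3), (3, 4), (2, 4), (1, 5)}),
    )
    return SnapshotSequence(
        nodes=(1, 2, 3, 4, 5),
        edges=windows,
        delta_t=1.0,
        window_starts=(0.0, 1.0, 2.0),
    )


def snapshots_to_events(snapshots: SnapshotSequence) -> pd.DataFrame:
    """Emit one event per (edge, window) at the window's midpoint.

    The output is a standard source/target/time table that re-windows to
    the original sequence under ``delta_t = snapshots.delta_t`` with
    unit-step (non-overlapping) windows, and coarsens or refines cleanly
    under window-size multipliers.
    """
    starts = snapshots.window_starts or tuple(
        k * snapshots.delta_t for k in range(snapshots.n_windows)
    )
    rows = [
        (u, v, start + 0.5 * snapshots.delta_t)
        for start, e_t in zip(starts, snapshots.edges)
        for u, v in sorted(e_t)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "time"])


def planted_triangles_config(
    n_triangles: int = 3,
    p_on: float = 0.9,
    noise_q: float = 0.02,
    n_nodes: int = 30,
    n_windows: int = 40,
) -> GeneratorConfig:
    """Parameter-recovery study: disjoint persistent triangles in noise.

    Triangle ``i`` occupies nodes ``3i..3i+2``; everything else is the
    Erdős–Rényi noise layer.  Defaults: 3 triangles with p_on = 0.9,
    q = 0.02, 30 nodes, 40 unit windows.
    """
    planted = tuple(
        PlantedCycle(nodes=(3 * i, 3 * i + 1, 3 * i + 2), p_on=p_on)
        for i in range(n_triangles)
    )
    return GeneratorConfig(
        n_nodes=n_nodes, n_windows=n_windows, planted=planted, noise_q=noise_q
    )


def hub_confounded_config(
    n_nodes: int = 61,
    n_windows: int = 40,
    p_on: float = 1.0,
    noise_q: float = 0.002,
    n_hubs: int = 6,
    hub_edges_per_window: int = 5,
) -> GeneratorConfig:
    """Attack benchmark: a cycle backbone carries connectivity, hubs carry degree.

    A chain of triangles ``{0,1,2}, {2,3,4}, ...`` spans every non-hub
    node, so global time-respecting connectivity routes through the
    chain's shared nodes — the intended cycle anchors.  The last
    ``n_hubs`` nodes sit outside the backbone and receive
    ``hub_edges_per_window`` transient random partners per window: they
    dominate every degree ranking, but their edges are re-drawn each
    window, so the cycles they incidentally close rarely recur and are
    removed by the persistence filter.  The core is kept large enough
    that two random hub partners are rarely backbone-adjacent, keeping
    hub-closed triangles transient by construction.  Removing top-TCN
    nodes severs the backbone; removing top-degree nodes only deletes
    redundant shortcuts.
    """
    core = n_nodes - n_hubs
    if core < 3 or core % 2 == 0:
        raise ValueError("need an odd number >= 3 of non-hub nodes for the chain")
    planted = tuple(
        PlantedCycle(nodes=(2 * i, 2 * i + 1, 2 * i + 2), p_on=p_on)
        for i in range((core - 1) // 2)
    )
    hubs = tuple(range(core, n_nodes))
    return GeneratorConfig(
        n_nodes=n_nodes,
        n_windows=n_windows,
        planted=planted,
        noise_q=noise_q,
        hubs=hubs,
        hub_edges_per_window=hub_edges_per_window,
    )
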