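"""Node-level persistence metrics (TCN/TCR, P2N/P2R) and baselines.

Temporal Cycle Number of node ``i`` over the window interval
``[t1, t2]``:

    TCN_i(t1, t2) = sum over cycles c containing i that are present in
                    at least one window of [t1, t2] of tau(c) * s(c, i)

with the structural-role weight fixed at ``s(c, i) = 1``, so TCN is a
persistence-weighted count of cycles a node belongs to.  ``tau`` is the
full-horizon duration of the cycle; the interval only decides which
cycles count as active.  The Temporal Cycle Ratio normalizes by the
node's cumulative windowed degree,

    TCR_i(t1, t2) = TCN_i(t1, t2) / (sum_{t=t1}^{t2} k_i(t) + eps),

separating nodes whose activity repeatedly converts into durable closure
from nodes that are merely busy.  P2N/P2R are the identical scores with
2-paths substituted for cycles.

Baselines: static betweenness and k-core index on the time-aggregated
union graph, and a temporal betweenness based on counting minimum-hop
earliest-arrival time-respecting paths on the same snapshot sequence.
"""

from __future__ import annotations

import heapq
import logging

import networkx as nx
import numpy as np
import pandas as pd

from .persistence import MotifInventory
from .temporal import SnapshotSequence, window_degrees

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_EPSILON",
    "tcn",
    "tcr",
    "participation_scores",
    "node_score_table",
    "static_betweenness",
    "kcore_index",
    "temporal_betweenness",
    "baseline_scores",
]

#: far below any integer degree sum, so printed ratios like 4/7 survive
#: rounding to two decimals
DEFAULT_EPSILON = 1e-9


def _resolve_interval(interval, n_windows: int) -> tuple[int, int]:
    if interval is None:
        return 1, n_windows
    t1, t2 = interval
    if not (1 <= t1 <= t2 <= n_windows):
        raise ValueError(f"interval {interval} outside 1..{n_windows}")
    return t1, t2


def _active_in(rec, t1: int, t2: int) -> bool:
    return any(rec.phi[t - 1] for t in range(t1, t2 + 1))


def participation_scores(
    inventory: MotifInventory,
    interval: tuple[int, int] | None = None,
    tau_min: float = 0.0,
    credit: str = "members",
) -> pd.Series:
    """Persistence-weighted motif participation per node.

    For every motif with ``tau >= tau_min`` that is present in at least
    one window of ``interval``, each credited node receives ``tau``.
    ``credit='members'`` credits every member node (the analogue of
    "cycles containing node i"); ``credit='center'`` credits only the
    center of a 2-path.
    """
    t1, t2 = _resolve_interval(interval, inventory.n_windows)
    scores = pd.Series(0.0, index=list(inventory.nodes))
    for rec in inventory:
        if rec.tau < tau_min or not _active_in(rec, t1, t2):
            continue
        if credit == "members":
            credited = rec.members
        elif credit == "center":
            credited = (rec.key[0],) if rec.kind == "2path" else rec.members
        else:
            raise ValueError(f"unknown credit mode {credit!r}")
        for v in credited:
            scores[v] += rec.tau
    return scores


def tcn(
    inventory: MotifInventory,
    node,
    interval: tuple[int, int] | None = None,
    tau_min: float = 0.0,
) -> float:
    """TCN of one node (see module docstring)."""
    if node not in set(inventory.nodes):
        raise KeyError(f"unknown node {node!r}")
    return float(participation_scores(inventory, interval, tau_min)[node])


def tcr(tcn_value: float, degree_sum: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """Cycle participation normalized by cumulative windowed degree."""
    if degree_sum < 0:
        raise ValueError("degree_sum must be nonnegative")
    if not epsilon > 0:
        raise ValueError("epsilon must be positive")
    return tcn_value / (degree_sum + epsilon)


def node_score_table(
    snapshots: SnapshotSequence,
    cycle_inventory: MotifInventory | None = None,
    twopath_inventory: MotifInventory | None = None,
    interval: tuple[int, int] | None = None,
    tau_min: float = 0.0,
    epsilon: float = DEFAULT_EPSILON,
    credit: str = "members",
    include_baselines: bool = False,
) -> pd.DataFrame:
    """Assemble the per-node score table, sorted by node identifier.

    Columns: ``tcn``, ``tcr``, ``p2n``, ``p2r``, ``degree_sum`` and,
    with ``include_baselines=True``, ``static_betweenness``,
    ``temporal_betweenness`` and ``kcore``.  Degree sums are taken over
    the same interval as motif activity.
    """
    t1, t2 = _resolve_interval(interval, snapshots.n_windows)
    deg = window_degrees(snapshots)
    degree_sum = deg.loc[:, t1:t2].sum(axis=1).astype(float)

    table = pd.DataFrame(index=list(snapshots.nodes))
    table["degree_sum"] = degree_sum
    denom = degree_sum + epsilon

    if cycle_inventory is not None:
        table["tcn"] = participation_scores(cycle_inventory, (t1, t2), tau_min)
        table["tcr"] = table["tcn"] / denom
    if twopath_inventory is not None:
        table["p2n"] = participation_scores(twopath_inventory, (t1, t2), tau_min, credit=credit)
        table["p2r"] = table["p2n"] / denom

    if include_baselines:
        table = table.join(baseline_scores(snapshots))

    order = [
        c for c in ["tcn", "tcr", "p2n", "p2r", "degree_sum",
                    "static_betweenness", "temporal_betweenness", "kcore"]
        if c in table.columns
    ]
    return table[order]


def static_betweenness(snapshots: SnapshotSequence) -> pd.Series:
    """Betweenness centrality on the time-aggregated union graph."""
    bc = nx.betweenness_centrality(snapshots.aggregated_graph(), normalized=True)
    return pd.Series(bc).reindex(list(snapshots.nodes)).fillna(0.0)


def kcore_index(snapshots: SnapshotSequence) -> pd.Series:
    """Core number of each node on the time-aggregated union graph."""
    core = nx.core_number(snapshots.aggregated_graph())
    return pd.Series(core, dtype=float).reindex(list(snapshots.nodes)).fillna(0.0)


def _earliest_arrival_and_hops(snapshots: SnapshotSequence, source, start_window: int):
    """Earliest-arrival window d(source, v) and minimum hop count at d.

    States are (node, window).  Within a window any number of hops is
    allowed; waiting at a node costs nothing.  Returns two dicts.
    """
    T = snapshots.n_windows
    INF = float("inf")
    hops = {v: INF for v in snapshots.nodes}  # min hops to be at v in current window
    hops[source] = 0
    arrival = {source: start_window}
    for t in range(start_window, T + 1):
        adj: dict = {}
        for u, v in snapshots.window(t):
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        # multi-hop relaxation within window t (BFS-like, hops +1 per edge)
        frontier = [v for v in adj if hops[v] < INF]
        heap = [(hops[v], v) for v in frontier]
        heapq.heapify(heap)
        seen = set()
        while heap:
            h, u = heapq.heappop(heap)
            if u in seen or h > hops[u]:
                continue
            seen.add(u)
            for w in adj.get(u, ()):
                if h + 1 < hops[w]:
                    hops[w] = h + 1
                    arrival.setdefault(w, t)
                    heapq.heappush(heap, (h + 1, w))
                elif w not in arrival:
                    arrival[w] = t
    return arrival, hops


def _count_paths(snapshots, source, target, d, h, start_window):
    """Count labeled min-hop earliest-arrival paths and interior-node visits.

    A labeled path is a sequence of (edge, window-label) steps with
    non-decreasing labels in [start_window, d], exactly ``h`` hops,
    ending at ``target`` with final label ``d``; node-simple by the
    min-hop argument.  Exhaustive DFS — intended for desk-scale
    baselines, not large networks.
    """
    windows = {t: {} for t in range(start_window, d + 1)}
    for t in range(start_window, d + 1):
        for u, v in snapshots.window(t):
            windows[t].setdefault(u, []).append(v)
            windows[t].setdefault(v, []).append(u)

    n_paths = 0
    interior_counts: dict = {}

    def dfs(node, t, used_hops, visited):
        nonlocal n_paths
        if node == target:
            if used_hops == h and t == d:
                n_paths += 1
                for v in visited:
                    if v not in (source, target):
                        interior_counts[v] = interior_counts.get(v, 0) + 1
            return
        if used_hops >= h:
            return
        for label in range(t, d + 1):
            for nxt in windows[label].get(node, ()):
                if nxt in visited:
                    continue
                dfs(nxt, label, used_hops + 1, visited | {nxt})

    dfs(source, start_window, 0, {source})
    return n_paths, interior_counts


def temporal_betweenness(
    snapshots: SnapshotSequence, start_windows=None
) -> pd.Series:
    """Fraction of earliest-arrival time-respecting paths through each node.

    For each start window ``t_s`` and ordered pair (i, j), paths are
    time-respecting (non-decreasing window labels, waiting allowed,
    unlimited hops per window), arrive at the earliest possible window
    and use the fewest hops among such arrivals; the score of an
    interior node v is the mean of sigma_ij(v)/sigma_ij over pairs,
    normalized by (n-1)(n-2) and averaged over start windows.  With a
    single window this reduces to static betweenness on that snapshot.

    Exhaustive path counting — suitable for small networks only.
    """
    nodes = list(snapshots.nodes)
    n = len(nodes)
    out = pd.Series(0.0, index=nodes)
    if n < 3:
        return out
    if start_windows is None:
        start_windows = range(1, snapshots.n_windows + 1)
    start_windows = list(start_windows)

    for t_s in start_windows:
        acc = pd.Series(0.0, index=nodes)
        for i in nodes:
            arrival, _ = _earliest_arrival_and_hops(snapshots, i, t_s)
            for j in nodes:
                if j == i or j not in arrival:
                    continue
                d = arrival[j]
                # min hops at the earliest-arrival window
                _, hops_at_d = _earliest_arrival_and_hops(
                    snapshots.replace_edges(snapshots.edges[: d]), i, t_s
                )
                h = hops_at_d[j]
                if not np.isfinite(h) or h == 0:
                    continue
                sigma, through = _count_paths(snapshots, i, j, d, int(h), t_s)
                if sigma == 0:
                    continue
                for v, cnt in through.items():
                    acc[v] += cnt / sigma
        out = out + acc / ((n - 1) * (n - 2))
    return out / len(start_windows)


def baseline_scores(snapshots: SnapshotSequence) -> pd.DataFrame:
    """Static betweenness, temporal betweenness and k-core per node."""
    return pd.DataFrame(
        {
            "static_betweenness": static_betweenness(snapshots),
            "temporal_betweenness": temporal_betweenness(snapshots),
            "kcore": kcore_index(snapshots),
        }
    )
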