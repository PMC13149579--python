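"""Windowed snapshot construction for temporal networks.

A temporal network is observed as a stream of timestamped interaction
events over a horizon ``[t_start, t_end)``.  For analysis the stream is
discretized into a sequence of (possibly overlapping) sliding windows of
duration ``delta_t`` and step ``step``; every event whose timestamp falls
into a window contributes an undirected edge to that window's snapshot.
Snapshots are simple graphs over one fixed node set ``V`` (the union of
all node identifiers seen anywhere in the stream): multi-edges within a
window collapse to one edge, directed records are symmetrized, and
self-loops are dropped.  A node that is inactive in a window stays in
``V`` with degree zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WindowingScheme",
    "SnapshotSequence",
    "undirected_edge",
    "build_snapshots",
    "window_degrees",
]


def undirected_edge(u: Hashable, v: Hashable) -> tuple:
    """Canonical unordered representation of the edge {u, v} (u != v)."""
    if u == v:
        raise ValueError(f"self-loop on node {u!r} is not a valid edge")
    return (u, v) if _lt(u, v) else (v, u)


def _lt(a, b) -> bool:
    try:
        return a < b
    except TypeError:
        # mixed node-identifier types: fall back to a stable total order
        return (str(type(a)), str(a)) < (str(type(b)), str(b))


def _sorted_nodes(nodes: Iterable) -> tuple:
    try:
        return tuple(sorted(set(nodes)))
    except TypeError:
        return tuple(sorted(set(nodes), key=lambda x: (str(type(x)), str(x))))


@dataclass(frozen=True)
class WindowingScheme:
    """Sliding-window discretization of the observation horizon.

    Parameters
    ----------
    delta_t:
        Window duration, in the time units of the event stream.
    step:
        Window step.  ``None`` means 50% overlap (``0.5 * delta_t``),
        the convention used throughout the sensitivity sweeps.  Must
        satisfy ``0 < step <= delta_t`` so consecutive windows leave no
        gap (a gap would silently drop events from every window).
    t_start, t_end:
        Observation horizon ``[t_start, t_end)``.  Either may be ``None``,
        in which case it is inferred from the event stream.

    Window ``k`` spans the half-open interval
    ``[t_start + k*step, t_start + k*step + delta_t)``; an event exactly
    at a window's right boundary belongs to the next window only.
    """

    delta_t: float
    step: float | None = None
    t_start: float | None = None
    t_end: float | None = None

    def __post_init__(self):
        if not (self.delta_t > 0):
            raise ValueError("delta_t must be positive")
        if self.step is None:
            object.__setattr__(self, "step", 0.5 * self.delta_t)
        if not (0 < self.step <= self.delta_t):
            raise ValueError(
                f"step must lie in (0, delta_t]; got step={self.step}, delta_t={self.delta_t}"
            )

    def window_starts(self, t_lo: float, t_hi: float) -> list[float]:
        """Left edges of the windows covering [t_lo, t_hi)."""
        span = t_hi - t_lo
        n = max(1, math.ceil((span - self.delta_t) / self.step) + 1)
        return [t_lo + k * self.step for k in range(n)]


@dataclass(frozen=True)
class SnapshotSequence:
    """A fixed node set ``V`` with one simple edge set per window.

    Windows are indexed 1..T_w in all user-facing APIs, matching the
    convention used for the persistence indicator phi(c, t).  Edges are
    canonical unordered pairs ``(u, v)`` with ``u < v``.
    """

    nodes: tuple
    edges: tuple  # tuple of frozensets of canonical edge pairs
    delta_t: float = 1.0
    window_starts: tuple | None = None

    def __post_init__(self):
        for t, e_t in enumerate(self.edges, start=1):
            for u, v in e_t:
                if u == v:
                    raise ValueError(f"self-loop {u!r} in window {t}")
                if u not in self.node_set or v not in self.node_set:
                    raise ValueError(f"edge ({u!r}, {v!r}) in window {t} leaves V")

    @property
    def node_set(self) -> frozenset:
        return frozenset(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_windows(self) -> int:
        return len(self.edges)

    def window(self, t: int) -> frozenset:
        """Edge set of window ``t`` (1-based)."""
        if not 1 <= t <= self.n_windows:
            raise IndexError(f"window index {t} outside 1..{self.n_windows}")
        return self.edges[t - 1]

    def graph(self, t: int) -> nx.Graph:
        """Snapshot ``G_t`` as a networkx graph over the full node set."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.window(t))
        return g

    def aggregated_graph(self) -> nx.Graph:
        """Time-aggregated union graph over all windows."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e_t in self.edges:
            g.add_edges_from(e_t)
        return g

    def replace_edges(self, new_edges: Sequence[frozenset]) -> "SnapshotSequence":
        return SnapshotSequence(
            nodes=self.nodes,
            edges=tuple(frozenset(e) for e in new_edges),
            delta_t=self.delta_t,
            window_starts=self.window_starts,
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format edge table with a 1-based window-index column."""
        rows = [
            (t, u, v)
            for t, e_t in enumerate(self.edges, start=1)
            for u, v in sorted(e_t)
        ]
        return pd.DataFrame(rows, columns=["window", "source", "target"])


def _coerce_events(events) -> pd.DataFrame:
    """Normalize an event stream to a DataFrame with source/target/time."""
    if isinstance(events, pd.DataFrame):
        df = events
    else:
        rows = list(events)
        if rows and len(rows[0]) == 4:
            df = pd.DataFrame(rows, columns=["source", "target", "time", "weight"])
        else:
            df = pd.DataFrame(rows, columns=["source", "target", "time"])
    missing = {"source", "target", "time"} - set(df.columns)
    if missing:
        raise ValueError(f"event stream lacks columns: {sorted(missing)}")
    return df


def build_snapshots(
    events,
    scheme: WindowingScheme,
    directed_input: bool = False,
) -> SnapshotSequence:
    """Bin timestamped events into windowed undirected simple snapshots.

    Parameters
    ----------
    events:
        DataFrame with columns ``source``, ``target``, ``time`` (and an
        optional ``weight``, parsed but ignored in the main analysis), or
        an iterable of ``(source, target, time[, weight])`` tuples.
    scheme:
        Window duration/step and (optionally explicit) horizon.
    directed_input:
        Declares that the raw records are directed.  Snapshots are
        undirected either way — directed records are symmetrized within
        each window — so this flag only affects log messages.

    Returns
    -------
    SnapshotSequence
        Chronologically ordered snapshots over the fixed node set
        ``V`` = union of all node identifiers in the stream.

    Notes
    -----
    Repeated interactions between one pair within a window collapse into
    a single edge.  Self-loops are dropped (their endpoints still enter
    ``V``).  With ``step < delta_t`` windows overlap, so one event can
    appear in several consecutive snapshots by design.
    """
    df = _coerce_events(events)

    if len(df) == 0:
        if scheme.t_start is None or scheme.t_end is None:
            raise ValueError(
                "an empty event stream needs an explicit t_start/t_end horizon"
            )
        starts = scheme.window_starts(scheme.t_start, scheme.t_end)
        return SnapshotSequence(
            nodes=(),
            edges=tuple(frozenset() for _ in starts),
            delta_t=scheme.delta_t,
            window_starts=tuple(starts),
        )

    times = pd.to_numeric(df["time"], errors="coerce").to_numpy(dtype=float)
    if not np.all(np.isfinite(times)):
        raise ValueError("event stream contains non-finite timestamps")

    nodes = _sorted_nodes(list(df["source"]) + list(df["target"]))

    loops = df["source"] == df["target"]
    n_loops = int(loops.sum())
    if n_loops:
        logger.info("dropping %d self-loop event(s)", n_loops)
        df = df[~loops]
        times = times[~loops.to_numpy()]

    t_lo = scheme.t_start if scheme.t_start is not None else float(times.min()) if len(times) else 0.0
    if scheme.t_end is not None:
        t_hi = scheme.t_end
    else:
        # inferred horizon: nudge past the last event so it lands in a window
        t_max = float(times.max()) if len(times) else t_lo + scheme.delta_t
        t_hi = t_max + 1e-9 * max(scheme.delta_t, abs(t_max), 1.0)
    if t_hi <= t_lo:
        raise ValueError(f"degenerate horizon [{t_lo}, {t_hi})")

    starts = scheme.window_starts(t_lo, t_hi)
    src = df["source"].to_numpy(dtype=object)
    dst = df["target"].to_numpy(dtype=object)

    per_window = []
    for w0 in starts:
        mask = (times >= w0) & (times < w0 + scheme.delta_t)
        e_t = frozenset(undirected_edge(u, v) for u, v in zip(src[mask], dst[mask]))
        per_window.append(e_t)

    return SnapshotSequence(
        nodes=nodes,
        edges=tuple(per_window),
        delta_t=scheme.delta_t,
        window_starts=tuple(starts),
    )


def window_degrees(snapshots: SnapshotSequence) -> pd.DataFrame:
    """Per-node, per-window degree table k_i(t).

    Returns a DataFrame indexed by node with one column per window
    (1-based).  Isolated nodes have degree 0, so every column sums to
    twice the window's edge count.
    """
    idx = list(snapshots.nodes)
    pos = {v: i for i, v in enumerate(idx)}
    k = np.zeros((len(idx), snapshots.n_windows), dtype=int)
    for t, e_t in enumerate(snapshots.edges):
        for u, v in e_t:
            k[pos[u], t] += 1
            k[pos[v], t] += 1
    return pd.DataFrame(k, index=idx, columns=range(1, snapshots.n_windows + 1))
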