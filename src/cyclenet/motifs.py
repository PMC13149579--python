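"""Motif enumeration in snapshot graphs: bounded simple cycles and 2-paths.

Cycles are the minimal closed redundancy units of a network; 2-paths
(open triads, one center with two distinct neighbors) are their open
counterparts and serve as the comparison motif family.  Both carry a
canonical identity so the same motif can be matched across windows:

* a cycle is identified by its sorted node set — distinct edge
  embeddings realizing a simple cycle on the same node set are grouped
  under one instance, but every embedding is retained so presence checks
  stay edge-exact;
* a 2-path is identified by ``(center, sorted endpoint pair)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Iterable

import networkx as nx

from .temporal import undirected_edge, _sorted_nodes

__all__ = [
    "CycleInstance",
    "TwoPathInstance",
    "enumerate_cycles",
    "enumerate_two_paths",
    "canonical_key",
]


@dataclass(frozen=True)
class CycleInstance:
    """All simple cycles found on one node set.

    ``nodes`` is the sorted node tuple (the canonical identity);
    ``embeddings`` holds one frozenset of edges per distinct simple
    cycle realized on exactly those nodes (a chordal node set such as a
    4-clique admits several).
    """

    nodes: tuple
    embeddings: frozenset  # frozenset of frozensets of canonical edges

    @property
    def length(self) -> int:
        return len(self.nodes)

    @property
    def key(self) -> tuple:
        return self.nodes

    @property
    def n_embeddings(self) -> int:
        return len(self.embeddings)


@dataclass(frozen=True)
class TwoPathInstance:
    """An open triad: edges {center, u} and {center, v} with u != v."""

    center: Hashable
    endpoints: tuple  # sorted pair (u, v)

    @property
    def nodes(self) -> tuple:
        return _sorted_nodes((self.center,) + self.endpoints)

    @property
    def length(self) -> int:
        return 3

    @property
    def edges(self) -> frozenset:
        u, v = self.endpoints
        return frozenset(
            {undirected_edge(self.center, u), undirected_edge(self.center, v)}
        )

    @property
    def embeddings(self) -> frozenset:
        return frozenset({self.edges})

    @property
    def key(self) -> tuple:
        return (self.center, self.endpoints)


def _cycle_edge_set(cycle_nodes: list) -> frozenset:
    m = len(cycle_nodes)
    return frozenset(
        undirected_edge(cycle_nodes[i], cycle_nodes[(i + 1) % m]) for i in range(m)
    )


def enumerate_cycles(
    snapshot_edges: Iterable[tuple], max_len: int = 5
) -> list[CycleInstance]:
    """Enumerate every simple cycle of length 3..max_len in a snapshot.

    Each undirected cycle is counted once (rotations/reflections are
    collapsed by the underlying enumeration); embeddings sharing a node
    set are grouped under one :class:`CycleInstance`.  Results are
    sorted by node key, so output is independent of edge input order.
    """
    if max_len < 3:
        raise ValueError(f"max_len must be >= 3, got {max_len}")
    g = nx.Graph()
    g.add_edges_from(snapshot_edges)
    grouped: dict[tuple, set] = {}
    for cyc in nx.simple_cycles(g, length_bound=max_len):
        if len(cyc) < 3:  # no self-loops / multi-edges expected, but be safe
            continue
        key = _sorted_nodes(cyc)
        grouped.setdefault(key, set()).add(_cycle_edge_set(cyc))
    return [
        CycleInstance(nodes=key, embeddings=frozenset(embs))
        for key, embs in sorted(grouped.items())
    ]


def enumerate_two_paths(
    snapshot_edges: Iterable[tuple], require_open: bool = False
) -> list[TwoPathInstance]:
    """Enumerate 2-paths: one instance per (center, unordered endpoint pair).

    Both edges {center, u} and {center, v} must be present.  By default
    the closing edge {u, v} may or may not exist; with
    ``require_open=True`` instances whose endpoints are directly linked
    are excluded (the strict open-triad reading — note this makes the
    presence indicator non-monotone under edge addition).
    """
    edges = {undirected_edge(u, v) for u, v in snapshot_edges}
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    out = []
    for center in sorted(adj, key=lambda x: (str(type(x)), str(x))):
        for u, v in combinations(sorted(adj[center], key=lambda x: (str(type(x)), str(x))), 2):
            if require_open and undirected_edge(u, v) in edges:
                continue
            out.append(TwoPathInstance(center=center, endpoints=(u, v)))
    return out


def canonical_key(instance) -> tuple:
    """Hashable identity invariant to traversal order and window.

    Cycles map to their sorted node tuple; 2-paths to
    ``(center, sorted endpoint pair)``.
    """
    return instance.key
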