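"""Independent brute-force oracles for cross-checking the pipeline.

Everything here recomputes quantities from first principles with
exhaustive enumeration (node subsets, permutations, time-expanded
graphs), deliberately sharing no code path with the package internals.
Intended for tiny instances only.
"""

from itertools import combinations, permutations

import networkx as nx
import numpy as np


def edge(u, v):
    return (u, v) if u < v else (v, u)


def brute_cycles(edges, max_len):
    """All simple cycles as {sorted node tuple: set of edge-set embeddings}.

    Tests every node subset of size 3..max_len for Hamiltonian closure:
    fix the minimum node first, enumerate permutations of the rest, keep
    one orientation per cycle (second node < last node), and record the
    edge set when every consecutive pair (and the closing pair) is an
    edge.
    """
    edges = {edge(u, v) for u, v in edges}
    nodes = sorted({v for e in edges for v in e})
    out = {}
    for size in range(3, max_len + 1):
        for subset in combinations(nodes, size):
            first, rest = subset[0], subset[1:]
            for perm in permutations(rest):
                if size > 2 and perm[0] > perm[-1]:
                    continue  # canonical orientation
                ring = (first,) + perm
                ring_edges = {
                    edge(ring[i], ring[(i + 1) % size]) for i in range(size)
                }
                if ring_edges <= edges:
                    out.setdefault(subset, set()).add(frozenset(ring_edges))
    return out


def brute_two_paths(edges):
    """All (center, endpoint-pair) triples with both incident edges present."""
    edges = {edge(u, v) for u, v in edges}
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return {
        (c, pair)
        for c in adj
        for pair in combinations(sorted(adj[c]), 2)
    }


def brute_cycle_taus(snapshots, max_len):
    """tau per cycle node set: re-enumerate every window, merge embeddings,
    then count windows containing any known embedding."""
    per_window = [brute_cycles(e_t, max_len) for e_t in snapshots.edges]
    merged = {}
    for found in per_window:
        for key, embs in found.items():
            merged.setdefault(key, set()).update(embs)
    taus = {}
    for key, embs in merged.items():
        count = sum(
            1
            for e_t in snapshots.edges
            if any(emb <= frozenset(edge(u, v) for u, v in e_t) for emb in embs)
        )
        taus[key] = count * snapshots.delta_t
    return taus


def brute_twopath_taus(snapshots):
    keys = set()
    for e_t in snapshots.edges:
        keys |= brute_two_paths(e_t)
    taus = {}
    for c, (u, v) in keys:
        need = {edge(c, u), edge(c, v)}
        count = sum(
            1
            for e_t in snapshots.edges
            if need <= {edge(a, b) for a, b in e_t}
        )
        taus[(c, (u, v))] = count * snapshots.delta_t
    return taus


def brute_tcn(snapshots, max_len, interval=None):
    """Direct Eq.-style sum: for each node, add tau of every cycle that
    contains it and is present in some window of the interval."""
    t1, t2 = interval if interval else (1, snapshots.n_windows)
    per_window = [brute_cycles(e_t, max_len) for e_t in snapshots.edges]
    merged = {}
    for found in per_window:
        for key, embs in found.items():
            merged.setdefault(key, set()).update(embs)
    taus = brute_cycle_taus(snapshots, max_len)
    scores = {v: 0.0 for v in snapshots.nodes}
    for key, embs in merged.items():
        active = any(
            any(emb <= frozenset(edge(u, v) for u, v in snapshots.edges[t - 1]) for emb in embs)
            for t in range(t1, t2 + 1)
        )
        if active:
            for v in key:
                scores[v] += taus[key]
    return scores


def brute_p2n(snapshots, interval=None):
    t1, t2 = interval if interval else (1, snapshots.n_windows)
    taus = brute_twopath_taus(snapshots)
    scores = {v: 0.0 for v in snapshots.nodes}
    for (c, (u, v)), tau in taus.items():
        need = {edge(c, u), edge(c, v)}
        active = any(
            need <= {edge(a, b) for a, b in snapshots.edges[t - 1]}
            for t in range(t1, t2 + 1)
        )
        if active:
            for w in (c, u, v):
                scores[w] += tau
    return scores


def time_expanded_digraph(snapshots, start_window=1):
    """Directed layered graph over (node, window) states."""
    g = nx.DiGraph()
    T = snapshots.n_windows
    for t in range(start_window, T + 1):
        for v in snapshots.nodes:
            g.add_node((v, t))
            if t > start_window:
                g.add_edge((v, t - 1), (v, t))  # wait
        for u, v in snapshots.edges[t - 1]:
            g.add_edge((u, t), (v, t))
            g.add_edge((v, t), (u, t))
    return g


def brute_earliest_arrival(snapshots, start_window=1):
    """d(i, j) via reachability in the time-expanded digraph."""
    g = time_expanded_digraph(snapshots, start_window)
    T = snapshots.n_windows
    d = {}
    for i in snapshots.nodes:
        reach = nx.descendants(g, (i, start_window)) | {(i, start_window)}
        for j in snapshots.nodes:
            hits = [t for (v, t) in reach if v == j]
            d[(i, j)] = min(hits) if hits else float("inf")
    return d


def brute_trr_ltcc(snapshots):
    d = brute_earliest_arrival(snapshots, 1)
    nodes = list(snapshots.nodes)
    n = len(nodes)
    reach = {(i, j) for (i, j), v in d.items() if i != j and np.isfinite(v)}
    trr = len(reach) / (n * (n - 1))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(reach)
    ltcc = max(len(c) for c in nx.connected_components(g))
    return trr, ltcc


def brute_efficiency(snapshots, start_window=1):
    d = brute_earliest_arrival(snapshots, start_window)
    nodes = list(snapshots.nodes)
    n = len(nodes)
    total = sum(
        1.0 / (d[(i, j)] - start_window + 1)
        for i in nodes
        for j in nodes
        if i != j and np.isfinite(d[(i, j)])
    )
    return total / (n * (n - 1))


def brute_temporal_betweenness(snapshots):
    """Naive enumeration of all labeled time-respecting simple paths.

    For each start window and ordered pair, enumerates every simple path
    with non-decreasing window labels, keeps those arriving at the
    earliest window with the fewest hops, and accumulates interior-node
    fractions; averaged over start windows, normalized by (n-1)(n-2).
    """
    nodes = list(snapshots.nodes)
    n = len(nodes)
    acc = {v: 0.0 for v in nodes}
    T = snapshots.n_windows
    windows = [
        {edge(u, v) for u, v in e_t} for e_t in snapshots.edges
    ]

    def all_paths(i, j, t_s):
        found = []  # (arrival, hops, interior tuple)

        def rec(node, label, visited):
            if node == j:
                found.append((label, len(visited) - 1, tuple(visited[1:-1])))
                return
            for t in range(label, T + 1):
                for e in windows[t - 1]:
                    if node in e:
                        nxt = e[0] if e[1] == node else e[1]
                        if nxt not in visited:
                            rec(nxt, t, visited + [nxt])

        for t in range(t_s, T + 1):
            for e in windows[t - 1]:
                if i in e:
                    nxt = e[0] if e[1] == i else e[1]
                    rec(nxt, t, [i, nxt])
        return found

    for t_s in range(1, T + 1):
        layer = {v: 0.0 for v in nodes}
        for i in nodes:
            for j in nodes:
                if i == j:
                    continue
                found = all_paths(i, j, t_s)
                if not found:
                    continue
                d = min(f[0] for f in found)
                at_d = [f for f in found if f[0] == d]
                h = min(f[1] for f in at_d)
                best = [f for f in at_d if f[1] == h]
                for _, _, interior in best:
                    for v in interior:
                        layer[v] += 1.0 / len(best)
        for v in nodes:
            acc[v] += layer[v] / ((n - 1) * (n - 2))
    return {v: acc[v] / T for v in nodes}
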