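"""Persistent-motif hypernetwork: tau_min filtering and co-participation.

Motifs whose persistence duration reaches a threshold ``tau_min`` are
encoded as hyperedges over their node sets, each weighted by its own
duration, ``w(e_c) = tau(c)``.  The co-participation adjacency

    A_H(i, j) = sum over hyperedges e containing both i and j of w(e)

accumulates, for every node pair, the durations of all retained motifs
in which the pair co-occurs (diagonal fixed at 0).  The threshold is
selected from percentiles {Q50, Q60, Q70, Q80, Q90} of the empirical
``tau`` distribution by maximizing the mean adjacent-interval rank
stability of the node scores, subject to retaining at least ``eta``
motifs; ties prefer the stricter (higher) percentile, favoring a compact
representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .metrics import DEFAULT_EPSILON, participation_scores
from .persistence import MotifInventory, PersistenceRecord
from .temporal import SnapshotSequence, window_degrees

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperedge",
    "Hypernetwork",
    "TauMinSelection",
    "build_hypernetwork",
    "select_tau_min",
]

DEFAULT_PERCENTILES = (50, 60, 70, 80, 90)


@dataclass(frozen=True)
class Hyperedge:
    members: tuple  # sorted node tuple of the generating motif
    weight: float  # w(e_c) = tau(c), optionally length-normalized
    source_key: tuple  # canonical identity of the generating motif


@dataclass
class Hypernetwork:
    """Weighted hypergraph of persistent motifs plus its adjacency A_H."""

    nodes: tuple
    hyperedges: tuple
    tau_min: float
    adjacency: np.ndarray  # dense symmetric |V| x |V|, zero diagonal

    @property
    def n_hyperedges(self) -> int:
        return len(self.hyperedges)

    def adjacency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.adjacency, index=list(self.nodes), columns=list(self.nodes)
        )

    def hyperedge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "weight": e.weight,
                "members": ",".join(str(v) for v in e.members),
                "source_key": str(e.source_key),
            }
            for e in self.hyperedges
        ]
        return pd.DataFrame(rows, columns=["weight", "members", "source_key"])


def build_hypernetwork(
    inventory: MotifInventory,
    tau_min: float,
    length_normalized: bool = False,
) -> Hypernetwork:
    """Encode motifs with ``tau >= tau_min`` as weighted hyperedges.

    ``length_normalized=True`` divides each weight by the motif length
    (an alternative weighting, off by default in the main analysis).
    """
    if tau_min < 0:
        raise ValueError("tau_min must be nonnegative")
    nodes = list(inventory.nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    kept = inventory.filter(tau_min)
    if not kept:
        logger.warning("tau_min=%s retains no motifs; hypernetwork is empty", tau_min)

    hyperedges = []
    A = np.zeros((len(nodes), len(nodes)))
    for rec in kept:
        w = rec.tau / rec.length if length_normalized else rec.tau
        hyperedges.append(Hyperedge(members=rec.members, weight=w, source_key=rec.key))
        for u, v in combinations(rec.members, 2):
            A[pos[u], pos[v]] += w
            A[pos[v], pos[u]] += w
    return Hypernetwork(
        nodes=inventory.nodes,
        hyperedges=tuple(hyperedges),
        tau_min=tau_min,
        adjacency=A,
    )


@dataclass
class TauMinSelection:
    """Outcome of the percentile-stability threshold selection."""

    tau_min: float
    percentile: int
    stats: pd.DataFrame  # percentile, tau_min, retained, stability, feasible
    metric: str
    eta: int
    subwindow: int


def _interval_scores(
    inventory: MotifInventory,
    degree: pd.DataFrame,
    interval: tuple[int, int],
    tau_min: float,
    metric: str,
    epsilon: float,
) -> pd.Series:
    raw = participation_scores(inventory, interval, tau_min)
    if metric == "tcn":
        return raw
    if metric == "tcr":
        t1, t2 = interval
        return raw / (degree.loc[:, t1:t2].sum(axis=1) + epsilon)
    raise ValueError(f"metric must be 'tcn' or 'tcr', got {metric!r}")


def select_tau_min(
    inventory: MotifInventory,
    snapshots: SnapshotSequence,
    metric: str = "tcn",
    eta: int = 10,
    subwindow: int = 5,
    percentiles=DEFAULT_PERCENTILES,
    epsilon: float = DEFAULT_EPSILON,
) -> TauMinSelection:
    """Pick tau_min from tau-distribution percentiles by ranking stability.

    For each candidate percentile (linear interpolation on the empirical
    ``tau`` distribution), node scores of ``metric`` are computed on
    every trailing sub-horizon of ``subwindow`` consecutive windows; the
    stability score is the mean Spearman rho between the rankings of
    consecutive sub-horizons.  Candidates retaining fewer than ``eta``
    motifs are infeasible.  Among feasible candidates the
    stability-maximizing one wins, ties broken toward the higher
    percentile.

    Raises
    ------
    ValueError
        If no candidate retains ``eta`` motifs — lower ``eta`` or use a
        smaller window duration so more motifs accumulate persistence.
    """
    if len(inventory) == 0:
        raise ValueError("empty motif inventory")
    if eta < 1:
        raise ValueError("eta must be >= 1")

    taus = np.asarray(inventory.taus(), dtype=float)
    degree = window_degrees(snapshots)
    T = snapshots.n_windows
    intervals = [
        (s, s + subwindow - 1) for s in range(1, max(T - subwindow + 1, 0) + 1)
    ]

    rows = []
    for p in percentiles:
        cand = float(np.percentile(taus, p))  # linear interpolation
        retained = int(np.sum(taus >= cand))
        feasible = retained >= eta
        stability = np.nan
        if feasible and len(intervals) >= 2:
            rhos = []
            prev = None
            for iv in intervals:
                scores = _interval_scores(inventory, degree, iv, cand, metric, epsilon)
                if prev is not None:
                    rho = spearmanr(prev.to_numpy(), scores.to_numpy()).statistic
                    rhos.append(0.0 if np.isnan(rho) else float(rho))
                prev = scores
            stability = float(np.mean(rhos)) if rhos else 0.0
        elif feasible:
            stability = 0.0
        rows.append(
            {
                "percentile": p,
                "tau_min": cand,
                "retained": retained,
                "stability": stability,
                "feasible": feasible,
            }
        )
    stats = pd.DataFrame(rows)

    feas = stats[stats["feasible"]]
    if feas.empty:
        raise ValueError(
            f"no tau_min candidate retains eta={eta} motifs "
            "(lower eta or shrink delta_t so persistence accumulates)"
        )
    best = feas.sort_values(
        ["stability", "percentile"], ascending=[False, False]
    ).iloc[0]
    return TauMinSelection(
        tau_min=float(best["tau_min"]),
        percentile=int(best["percentile"]),
        stats=stats,
        metric=metric,
        eta=eta,
        subwindow=subwindow,
    )
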