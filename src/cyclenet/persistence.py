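"""Persistence tracking of motifs across windowed snapshots.

A motif instance ``c`` is *present* in window ``t`` when all edges of at
least one of its recorded embeddings are contained in the snapshot's
edge set; the binary presence indicator is ``phi(c, t)``.  Its
persistence duration is

    tau(c) = sum_t phi(c, t) * delta_t,

i.e. the total time, in window-duration units, during which the motif is
available.  Since ``delta_t`` is fixed within a dataset, ``tau`` is
monotonically equivalent to the number of windows in which the motif
appears; absolute ``tau`` values are only meaningful within one dataset.

The inventory is built by detecting motifs in every window, merging
instances by canonical key, and then re-evaluating ``phi`` in *every*
window for every known instance.  This retroactive evaluation is the
executable reading of node-set matching: presence is defined purely by
snapshot containment, so an embedding discovered late still counts in
earlier windows where its edges happened to be present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .motifs import CycleInstance, TwoPathInstance, enumerate_cycles, enumerate_two_paths
from .temporal import SnapshotSequence

logger = logging.getLogger(__name__)

__all__ = ["PersistenceRecord", "MotifInventory", "evaluate_phi", "track"]


def evaluate_phi(instance, snapshot_edges) -> int:
    """Presence indicator of a motif instance in one snapshot.

    Returns 1 iff at least one recorded edge embedding is a subset of
    the snapshot's edge set, else 0.
    """
    edges = frozenset(snapshot_edges)
    return int(any(emb <= edges for emb in instance.embeddings))


@dataclass(frozen=True)
class PersistenceRecord:
    """Persistence summary of one motif instance over the horizon."""

    key: tuple
    kind: str  # "cycle" | "2path"
    members: tuple  # sorted node tuple of the motif
    embeddings: frozenset
    phi: tuple  # 0/1 presence vector over windows 1..T_w
    tau: float  # duration in time units: tau_windows * delta_t
    tau_windows: int
    first_seen: int  # 1-based window indices
    last_seen: int

    @property
    def length(self) -> int:
        return len(self.members)


@dataclass
class MotifInventory:
    """Mapping from canonical key to :class:`PersistenceRecord`."""

    records: dict
    kind: str
    nodes: tuple
    n_windows: int
    delta_t: float

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __getitem__(self, key) -> PersistenceRecord:
        return self.records[key]

    def __contains__(self, key) -> bool:
        return key in self.records

    def taus(self) -> list[float]:
        return [rec.tau for rec in self]

    def filter(self, tau_min: float) -> list[PersistenceRecord]:
        """Records with tau >= tau_min, sorted by (-tau, key)."""
        kept = [rec for rec in self if rec.tau >= tau_min]
        return sorted(kept, key=lambda r: (-r.tau, r.key))

    def to_frame(self) -> pd.DataFrame:
        """Persistence table: one row per motif, phi as a 0/1 string."""
        rows = [
            {
                "key": str(rec.key),
                "type": rec.kind,
                "length": rec.length,
                "tau_time": rec.tau,
                "tau_windows": rec.tau_windows,
                "first_seen": rec.first_seen,
                "last_seen": rec.last_seen,
                "phi": "".join(str(x) for x in rec.phi),
            }
            for rec in sorted(self, key=lambda r: (-r.tau, r.key))
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "key", "type", "length", "tau_time", "tau_windows",
                "first_seen", "last_seen", "phi",
            ],
        )


def _detect(edges, family: str, max_len: int, require_open: bool):
    if family in ("cycles", "cycle"):
        return enumerate_cycles(edges, max_len=max_len)
    if family in ("2paths", "2path", "two_paths"):
        return enumerate_two_paths(edges, require_open=require_open)
    raise ValueError(f"unknown motif family {family!r}")


def track(
    snapshots: SnapshotSequence,
    family: str = "cycles",
    max_len: int = 5,
    require_open: bool = False,
) -> MotifInventory:
    """Build the motif inventory with phi and tau for every instance.

    Detection runs in every window; instances are merged by canonical
    key (cycles additionally merge edge embeddings found in different
    windows).  ``phi`` is then evaluated retroactively in every window,
    so a motif that disappears and later re-forms keeps accumulating
    ``tau``, and ``tau > 0`` for every record by construction.
    """
    merged_embeddings: dict[tuple, set] = {}
    members: dict[tuple, tuple] = {}
    for e_t in snapshots.edges:
        for inst in _detect(e_t, family, max_len, require_open):
            k = inst.key
            merged_embeddings.setdefault(k, set()).update(inst.embeddings)
            members.setdefault(k, inst.nodes)

    kind = "cycle" if family.startswith("cycle") else "2path"
    records: dict[tuple, PersistenceRecord] = {}
    for k in sorted(merged_embeddings):
        embs = frozenset(merged_embeddings[k])
        phi = tuple(
            int(any(emb <= e_t for emb in embs)) for e_t in snapshots.edges
        )
        tau_w = sum(phi)
        present = [t for t, p in enumerate(phi, start=1) if p]
        records[k] = PersistenceRecord(
            key=k,
            kind=kind,
            members=members[k],
            embeddings=embs,
            phi=phi,
            tau=tau_w * snapshots.delta_t,
            tau_windows=tau_w,
            first_seen=present[0],
            last_seen=present[-1],
        )
        dissolutions = sum(
            1 for a, b in zip(phi, phi[1:]) if a == 1 and b == 0
        )
        if dissolutions:
            logger.debug("motif %s dissolved %d time(s)", k, dissolutions)

    return MotifInventory(
        records=records,
        kind=kind,
        nodes=snapshots.nodes,
        n_windows=snapshots.n_windows,
        delta_t=snapshots.delta_t,
    )
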