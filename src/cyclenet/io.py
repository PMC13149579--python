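"""Readers and writers for delimited temporal edge lists.

Two dialects of whitespace/character-delimited text are supported:

* ``tij`` — SocioPatterns order: timestamp, node i, node j;
* ``uvt`` — source, target, timestamp and an optional fourth weight
  column (weights are parsed but ignored by the main pipeline).

Lines starting with ``#`` are comments.  Column order can also be given
explicitly via ``columns``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .temporal import SnapshotSequence

__all__ = ["read_events", "write_events", "write_snapshots", "read_snapshots"]

_DIALECTS = {
    "tij": ["time", "source", "target"],
    "uvt": ["source", "target", "time"],
}


def read_events(
    path,
    dialect: str = "uvt",
    sep: str | None = None,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Read a delimited edge list into a source/target/time[, weight] table.

    ``sep=None`` means any whitespace.  A fourth column, when present,
    is read as ``weight``.
    """
    if columns is None:
        if dialect not in _DIALECTS:
            raise ValueError(f"unknown dialect {dialect!r}; use one of {sorted(_DIALECTS)}")
        columns = _DIALECTS[dialect]
    try:
        df = pd.read_csv(
            path,
            sep=sep if sep is not None else r"\s+",
            comment="#",
            header=None,
            engine="python",
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["source", "target", "time"])
    ncol = df.shape[1]
    if ncol < len(columns):
        raise ValueError(
            f"{path}: expected >= {len(columns)} columns for dialect, found {ncol}"
        )
    names = list(columns) + [
        "weight" if ncol == len(columns) + 1 else f"extra_{k}"
        for k in range(ncol - len(columns))
    ]
    df.columns = names
    df["time"] = pd.to_numeric(df["time"])
    return df[[c for c in ["source", "target", "time", "weight"] if c in df.columns]]


def write_events(events: pd.DataFrame, path, dialect: str = "uvt") -> None:
    """Write an event table in the given dialect (whitespace-delimited)."""
    cols = _DIALECTS[dialect]
    events[cols].to_csv(path, sep="\t", header=False, index=False)


def write_snapshots(snapshots: SnapshotSequence, path) -> None:
    """Single long-format file: window index, source, target (tab-separated)."""
    df = snapshots.to_long_frame()
    with open(path, "w") as fh:
        fh.write(f"# delta_t={snapshots.delta_t}\n")
        fh.write(f"# nodes={','.join(str(v) for v in snapshots.nodes)}\n")
        fh.write(f"# n_windows={snapshots.n_windows}\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_snapshots(path) -> SnapshotSequence:
    """Round-trip reader for :func:`write_snapshots` output."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["window", "source", "target"],
    )
    n_windows = int(meta["n_windows"])

    def _parse(tok: str):
        try:
            return int(tok)
        except ValueError:
            return tok

    nodes = tuple(_parse(t) for t in meta["nodes"].split(",")) if meta.get("nodes") else ()
    windows = []
    for t in range(1, n_windows + 1):
        part = df[df["window"] == t]
        windows.append(
            frozenset(
                (u, v) if u < v else (v, u)
                for u, v in zip(part["source"], part["target"])
            )
        )
    return SnapshotSequence(
        nodes=nodes, edges=tuple(windows), delta_t=float(meta.get("delta_t", 1.0))
    )
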