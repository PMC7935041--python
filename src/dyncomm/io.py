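"""Plain-text readers and writers for every pipeline artifact.

Layers travel as long-format edge lists (TSV: day, node_i, node_j,
weight with i < j), partitions as node-by-day label tables, node
metadata as TSV, hormone panels as CSV, and events plus provenance as
JSON.  All files carry headers; node identifiers on disk come from the
metadata's ``node_id`` column, never from positional order, and layers
are keyed by 1-based study day.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import ReorganizationEvent
from .network import MultilayerNetwork, NodeMetadata, Partition

__all__ = [
    "write_multilayer",
    "read_multilayer",
    "write_metadata",
    "read_metadata",
    "write_hormones",
    "read_hormones",
    "write_partition",
    "read_partition",
    "write_events",
    "read_events",
    "write_provenance",
]

HORMONE_COLUMNS = ("day", "estradiol", "progesterone", "testosterone", "lh", "fsh")


def write_multilayer(net: MultilayerNetwork, path: str | Path) -> Path:
    """Long-format edge list TSV with one row per (day, i < j) pair."""
    path = Path(path)
    iu = np.triu_indices(net.n_nodes, k=1)
    frames = []
    ids = np.asarray(net.node_ids, dtype=object)
    for l, day in enumerate(net.layer_days):
        w = net.A[:, :, l][iu]
        frames.append(
            pd.DataFrame(
                {
                    "day": day,
                    "node_i": ids[iu[0]],
                    "node_j": ids[iu[1]],
                    "weight": w,
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_multilayer(path: str | Path, allow_gaps: bool = False) -> MultilayerNetwork:
    """Rebuild a multilayer network from an edge-list TSV.

    The matrix is symmetrized (maximum of the two triangles), the
    diagonal zeroed and missing pairs left at 0.  Days are sorted
    ascending; a gap in the day sequence is an error unless
    ``allow_gaps`` relabels layers contiguously (original days are kept
    as ``layer_days``).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"day", "node_i", "node_j", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: edge list must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    neg = df.index[df["weight"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative weight at row {int(neg[0]) + 2}")
    dup = df.duplicated(subset=["day", "node_i", "node_j"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ValueError(f"{path}: duplicate (day, node_i, node_j) at row {row}")
    days = sorted(df["day"].unique())
    if days != list(range(days[0], days[0] + len(days))):
        if not allow_gaps:
            raise ValueError(
                f"{path}: day sequence has gaps ({days}); pass allow_gaps=True to "
                "relabel layers contiguously"
            )
        warnings.warn(
            f"{path}: day sequence has gaps; layers relabeled contiguously, "
            "original days kept as layer_days",
            stacklevel=2,
        )
    node_ids = sorted(set(df["node_i"]) | set(df["node_j"]))
    pos = {nid: k for k, nid in enumerate(node_ids)}
    N, L = len(node_ids), len(days)
    A = np.zeros((N, N, L))
    day_pos = {d: l for l, d in enumerate(days)}
    li = df["day"].map(day_pos).to_numpy()
    ii = df["node_i"].map(pos).to_numpy()
    jj = df["node_j"].map(pos).to_numpy()
    ww = df["weight"].to_numpy(dtype=float)
    np.maximum.at(A, (ii, jj, li), ww)
    A = np.maximum(A, A.transpose(1, 0, 2))
    idx = np.arange(N)
    A[idx, idx, :] = 0.0
    return MultilayerNetwork(A, node_ids=node_ids, layer_days=[int(d) for d in days])


def write_metadata(meta: NodeMetadata, path: str | Path) -> Path:
    path = Path(path)
    meta.table.reset_index().to_csv(path, sep="\t", index=False)
    return path


def read_metadata(path: str | Path) -> NodeMetadata:
    df = pd.read_csv(path, sep="\t")
    missing = {"node_id", *NodeMetadata.COLUMNS} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    return NodeMetadata(df)


def write_hormones(panel: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    panel.to_csv(path, index=False)
    return path


def read_hormones(path: str | Path) -> pd.DataFrame:
    """Hormone panel CSV; requires the standard header and gap-free days."""
    df = pd.read_csv(path)
    missing = set(HORMONE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: hormone panel missing columns {sorted(missing)}")
    if (df[list(HORMONE_COLUMNS[1:])].to_numpy() < 0).any():
        raise ValueError(f"{path}: hormone concentrations must be nonnegative")
    days = df["day"].to_list()
    if days != list(range(int(days[0]), int(days[0]) + len(days))):
        raise ValueError(f"{path}: hormone panel days must be consecutive")
    return df


def write_partition(
    part: Partition, node_ids, path: str | Path, layer_days=None
) -> Path:
    """Node-by-day label table; columns named by 1-based study day."""
    path = Path(path)
    days = layer_days if layer_days is not None else range(1, part.n_layers + 1)
    df = pd.DataFrame(part.labels, index=pd.Index(node_ids, name="node_id"),
                      columns=[str(d) for d in days])
    df.reset_index().to_csv(path, sep="\t", index=False)
    return path


def read_partition(path: str | Path) -> tuple[Partition, list]:
    df = pd.read_csv(path, sep="\t")
    if "node_id" not in df.columns:
        raise ValueError(f"{path}: partition table needs a node_id column")
    node_ids = df["node_id"].tolist()
    labels = df.drop(columns="node_id").to_numpy(dtype=np.int64)
    return Partition(labels), node_ids


def write_events(events: list[ReorganizationEvent], path: str | Path) -> Path:
    path = Path(path)
    payload = [dataclasses.asdict(e) | {"size": e.size} for e in events]
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_events(path: str | Path) -> list[ReorganizationEvent]:
    raw = json.loads(Path(path).read_text())
    return [
        ReorganizationEvent(
            day=e["day"],
            kind=e["kind"],
            node_set=tuple(e["node_set"]),
            source_community=e["source_community"],
            target_community=e["target_community"],
            duration=e["duration"],
        )
        for e in raw
    ]


def write_provenance(path: str | Path, config: dict, seed: int | None = None) -> Path:
    """Provenance JSON: full configuration, its hash, seed and version."""
    from . import __version__

    path = Path(path)
    blob = json.dumps(config, sort_keys=True, default=str)
    payload = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "dyncomm_version": __version__,
    }
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
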