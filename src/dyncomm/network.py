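"""Core containers for multilayer (multislice) network analysis.

A temporal functional-connectivity experiment yields one weighted,
undirected association matrix per session (here: per day).  Stacking the
``L`` daily ``N x N`` matrices gives a multilayer network in which each
node is additionally coupled to itself in adjacent layers.  Community
structure on this object is scored by multislice modularity

    Q = (1/2mu) * sum_{ijlr} [ (A_ijl - gamma * k_il k_jl / (2 m_l)) d_lr
                               + d_ij * omega_jlr ] * d(g_il, g_jr)

where ``A_ijl`` is the weight between nodes ``i`` and ``j`` in layer
``l``, ``k_il`` the strength of node ``i`` in layer ``l``, ``2 m_l`` the
total strength of layer ``l``, ``gamma`` the structural resolution,
``omega`` the temporal coupling between a node and itself in adjacent
layers, ``g_il`` the community label of node ``i`` in layer ``l`` and
``d`` the Kronecker delta.  The normaliser uses the convention
``2 mu = sum_l sum_ij A_ijl + 2 * omega * N * (L - 1)`` so that coupling
weight counts toward the total edge weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MultilayerNetwork",
    "ModularityParams",
    "Partition",
    "PartitionEnsemble",
    "NodeMetadata",
    "canonicalize_labels",
]


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber community labels by first appearance in (layer, node) order.

    Labels become contiguous integers starting at 0, so two partitions that
    differ only by a permutation of label names compare equal elementwise.

    Parameters
    ----------
    labels : (N, L) integer array.
    """
    labels = np.asarray(labels)
    flat = labels.T.ravel()  # layer-major: all nodes of layer 0, then layer 1, ...
    _, first_idx, inverse = np.unique(flat, return_index=True, return_inverse=True)
    order = np.argsort(np.argsort(first_idx))
    return order[inverse].reshape(labels.shape[::-1]).T.astype(np.int64)


@dataclass(frozen=True)
class ModularityParams:
    """Resolution parameters of the multislice quality function.

    gamma : structural resolution; > 1 favours more, smaller communities.
    omega : temporal coupling between a node and itself in adjacent
        layers; larger values favour labels that persist across days.
        Coupling is restricted to adjacent layers (|l - r| = 1).
    """

    gamma: float = 1.0
    omega: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")


class MultilayerNetwork:
    """An N x N x L stack of symmetric, nonnegative, zero-diagonal layers.

    Parameters
    ----------
    layers : (N, N, L) array, or sequence of L (N, N) arrays.
    node_ids : optional sequence of node identifiers (default 0..N-1).
    layer_days : optional 1-based study-day index per layer (default 1..L).

    Strengths ``k_il``, per-layer totals ``2 m_l`` and the modularity
    normaliser are always derived from the weight tensor on access, never
    cached, so they cannot go stale.
    """

    def __init__(
        self,
        layers: np.ndarray | Sequence[np.ndarray],
        node_ids: Sequence[str | int] | None = None,
        layer_days: Sequence[int] | None = None,
    ) -> None:
        if not isinstance(layers, np.ndarray):
            layers = np.stack([np.asarray(m, dtype=float) for m in layers], axis=-1)
        A = np.asarray(layers, dtype=float)
        if A.ndim != 3 or A.shape[0] != A.shape[1]:
            raise ValueError(f"expected (N, N, L) tensor, got shape {A.shape}")
        if A.shape[2] < 1:
            raise ValueError("at least one layer required")
        if np.any(A < 0):
            raise ValueError("edge weights must be nonnegative")
        for l in range(A.shape[2]):
            if not np.allclose(A[:, :, l], A[:, :, l].T):
                raise ValueError(f"layer {l} is not symmetric")
        A = 0.5 * (A + A.transpose(1, 0, 2))  # exact symmetry
        idx = np.arange(A.shape[0])
        A[idx, idx, :] = 0.0
        self.A = A
        self.node_ids = list(node_ids) if node_ids is not None else list(range(A.shape[0]))
        self.layer_days = (
            list(layer_days) if layer_days is not None else list(range(1, A.shape[2] + 1))
        )
        if len(self.node_ids) != A.shape[0]:
            raise ValueError("node_ids length does not match N")
        if len(self.layer_days) != A.shape[2]:
            raise ValueError("layer_days length does not match L")

    # -- derived quantities -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_layers(self) -> int:
        return self.A.shape[2]

    def strengths(self) -> np.ndarray:
        """Per-layer node strengths k_il, shape (N, L)."""
        return self.A.sum(axis=1)

    def layer_totals(self) -> np.ndarray:
        """Total strength 2 m_l per layer, shape (L,)."""
        return self.A.sum(axis=(0, 1))

    def two_mu(self, omega: float) -> float:
        """Modularity normaliser 2 mu; interlayer coupling counts in it."""
        return float(self.layer_totals().sum()) + 2.0 * omega * self.n_nodes * (self.n_layers - 1)


@dataclass
class Partition:
    """Node-by-layer community labels from one optimisation run."""

    labels: np.ndarray  # (N, L) int
    params: ModularityParams = field(default_factory=ModularityParams)
    seed: int | None = None
    quality: float | None = None  # achieved Q

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D (node x layer) array")

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    @property
    def n_layers(self) -> int:
        return self.labels.shape[1]

    def canonicalized(self) -> "Partition":
        return Partition(
            canonicalize_labels(self.labels), self.params, self.seed, self.quality
        )

    def n_communities_per_layer(self) -> np.ndarray:
        return np.array([len(np.unique(self.labels[:, l])) for l in range(self.n_layers)])

    def n_communities(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class PartitionEnsemble:
    """Ordered collection of partitions from repeated seeded runs."""

    runs: list[Partition]

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("ensemble must contain at least one run")
        shape = self.runs[0].labels.shape
        params = self.runs[0].params
        for r in self.runs:
            if r.labels.shape != shape:
                raise ValueError("all runs must share (N, L)")
            if r.params != params:
                raise ValueError("all runs must share modularity parameters")

    def __len__(self) -> int:
        return len(self.runs)

    def __iter__(self):
        return iter(self.runs)

    def __getitem__(self, i: int) -> Partition:
        return self.runs[i]

    @property
    def params(self) -> ModularityParams:
        return self.runs[0].params

    def label_stack(self) -> np.ndarray:
        """(R, N, L) stacked labels."""
        return np.stack([r.labels for r in self.runs])


class NodeMetadata:
    """Node -> (network, subnetwork, hemisphere, contralateral homolog) map.

    Wraps a DataFrame indexed by ``node_id`` with columns ``name``,
    ``network``, ``subnetwork``, ``hemisphere`` (L/R/NA) and
    ``homolog_id``.  The homolog relation must be symmetric.
    """

    COLUMNS = ("name", "network", "subnetwork", "hemisphere", "homolog_id")

    def __init__(self, table: pd.DataFrame) -> None:
        table = table.copy()
        if table.index.name != "node_id":
            if "node_id" not in table.columns:
                raise ValueError("metadata needs a node_id column or index")
            table = table.set_index("node_id")
        for col in self.COLUMNS:
            if col not in table.columns:
                raise ValueError(f"metadata missing column {col!r}")
        if table.index.has_duplicates:
            raise ValueError("duplicate node_id in metadata")
        self.table = table
        # homolog symmetry check
        hom = table["homolog_id"]
        for nid, h in hom.items():
            if pd.isna(h):
                continue
            if h not in table.index or not (hom.loc[h] == nid):
                raise ValueError(f"homolog relation not symmetric at node {nid!r}")

    @property
    def node_ids(self) -> list:
        return list(self.table.index)

    @property
    def networks(self) -> pd.Series:
        return self.table["network"]

    def network_names(self) -> list[str]:
        return sorted(self.table["network"].unique())

    def network_indices(self, node_ids: Sequence) -> dict[str, np.ndarray]:
        """Positional indices (into ``node_ids``) of each network's members."""
        nets = self.table["network"].reindex(node_ids)
        return {
            name: np.flatnonzero((nets == name).to_numpy())
            for name in self.network_names()
        }

    def homolog_pairs(self, node_ids: Sequence) -> list[tuple[int, int]]:
        """Positional index pairs (i, j), i < j, of contralateral homologs."""
        pos = {nid: k for k, nid in enumerate(node_ids)}
        pairs = []
        for nid, h in self.table["homolog_id"].items():
            if pd.isna(h) or nid not in pos or h not in pos:
                continue
            i, j = pos[nid], pos[h]
            if i < j:
                pairs.append((i, j))
        return pairs
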