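"""Ensemble consensus, community significance nulls, and flexibility cutoffs.

The community optimizer is stochastic, so partitions are estimated 150
times (by default) per parameter combination.  The consensus partition
is the ensemble medoid: the member whose mean pairwise similarity
(adjusted Rand index on the flattened node-by-layer labels) to all other
members is maximal.  Community significance is assessed against a
size-matched random-node-set null, and unusually flexible nodes are
identified against a pooled percentile cutoff with a per-network
binomial overrepresentation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from sklearn.metrics import adjusted_rand_score

from .dynamics import node_flexibility
from .network import MultilayerNetwork, NodeMetadata, Partition, PartitionEnsemble

__all__ = [
    "partition_similarity",
    "consensus_partition",
    "ConsensusPartition",
    "community_significance",
    "SignificanceReport",
    "flexibility_cutoff",
    "FlexibilityCutoffReport",
]


def partition_similarity(p1: Partition, p2: Partition, method: str = "ari") -> float:
    """Similarity of two node-by-layer partitions on flattened labels.

    ``method="ari"`` (default) is the adjusted Rand index; ``"zrand"``
    is the standardized Rand z-score of Traud et al., rescaled by its
    theoretical maximum so it also lands in [-1, 1]-like range.
    """
    a = np.asarray(p1.labels)
    b = np.asarray(p2.labels)
    if a.shape != b.shape:
        raise ValueError(f"partition shapes differ: {a.shape} vs {b.shape}")
    if method == "ari":
        return float(adjusted_rand_score(a.ravel(), b.ravel()))
    if method == "zrand":
        return _zrand(a.ravel(), b.ravel())
    raise ValueError(f"unknown similarity method {method!r}")


def _zrand(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized number of co-classified pairs under random permutation."""
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(cont, (ai, bi), 1)
    nij = special.comb(cont, 2).sum()
    row = special.comb(cont.sum(axis=1), 2).sum()
    col = special.comb(cont.sum(axis=0), 2).sum()
    M = special.comb(n, 2)
    mean = row * col / M
    # hypergeometric variance of the pair-count overlap
    var = (
        mean * (1 - mean / M)
        + (row - mean) * (col - mean) / (M - 1) * (1 - (row + col - 2 * mean) / (M - 2))
        if M > 2
        else 0.0
    )
    if var <= 0:
        return 0.0
    return float((nij - mean) / np.sqrt(var))


@dataclass
class ConsensusPartition:
    """Ensemble medoid and its mean similarity to the other members."""

    partition: Partition
    run_index: int
    mean_similarity: float


def consensus_partition(ens: PartitionEnsemble, method: str = "ari") -> ConsensusPartition:
    """Pick the ensemble member with maximal mean similarity to all others.

    Ties are broken toward the lowest run index.  For a single-run
    ensemble the mean similarity is defined as 1.
    """
    R = len(ens)
    if R == 1:
        return ConsensusPartition(ens[0], 0, 1.0)
    sim = np.ones((R, R))
    for i in range(R):
        for j in range(i + 1, R):
            s = partition_similarity(ens[i], ens[j], method=method)
            sim[i, j] = sim[j, i] = s
    means = (sim.sum(axis=1) - 1.0) / (R - 1)
    best = int(np.argmax(means))  # argmax returns the first (lowest) index on ties
    return ConsensusPartition(ens[best], best, float(means[best]))


@dataclass
class SignificanceReport:
    """Per-community p-values from the size-matched random-node-set null."""

    communities: list[int]
    p_values: dict[int, float]
    significant: dict[int, bool]
    observed: dict[int, float]
    n_draws: int
    alpha: float


def community_significance(
    net: MultilayerNetwork,
    part: Partition,
    n_draws: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> SignificanceReport:
    """Test each community's internal weight against random node sets.

    The observed statistic for a community is the mean intralayer edge
    weight between its members, pooled over the layers in which the
    community has at least two members.  The null re-draws, ``n_draws``
    times, uniformly random node sets of the same per-layer sizes and
    computes the same pooled statistic; the p-value uses add-one
    smoothing, ``p = (1 + #{null >= observed}) / (1 + n_draws)``.
    Communities that never reach size two get p = 1.  Null draws are
    seeded from ``seed`` and the community's per-layer size profile, so
    p-values are invariant to community relabeling.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    g = part.labels
    N, L = g.shape
    comms = sorted(int(c) for c in np.unique(g))
    p_values: dict[int, float] = {}
    observed: dict[int, float] = {}

    def pooled_mean(member_sets: list[tuple[int, np.ndarray]]) -> float:
        tot, cnt = 0.0, 0
        for l, members in member_sets:
            sub = net.A[np.ix_(members, members, [l])][:, :, 0]
            s = len(members)
            tot += sub.sum() / 2.0
            cnt += s * (s - 1) // 2
        return tot / cnt if cnt else np.nan

    for c in comms:
        layer_members = [
            (l, np.flatnonzero(g[:, l] == c)) for l in range(L)
        ]
        layer_members = [(l, m) for l, m in layer_members if len(m) >= 2]
        if not layer_members:
            p_values[c] = 1.0
            observed[c] = np.nan
            continue
        obs = pooled_mean(layer_members)
        observed[c] = obs
        exceed = 0
        sizes = [(l, len(m)) for l, m in layer_members]
        rng = np.random.default_rng(
            [seed] + [v for pair in sizes for v in pair]
        )
        for _ in range(n_draws):
            draw = [(l, rng.choice(N, size=s, replace=False)) for l, s in sizes]
            if pooled_mean(draw) >= obs:
                exceed += 1
        p_values[c] = (1 + exceed) / (1 + n_draws)
    significant = {c: p_values[c] < alpha for c in comms}
    return SignificanceReport(comms, p_values, significant, observed, n_draws, alpha)


@dataclass
class FlexibilityCutoffReport:
    """Per-network exceedance of the pooled high-flexibility cutoff."""

    cutoff: float
    percentile: float
    node_mean_flexibility: np.ndarray  # (N,) across-run mean
    exceeds: np.ndarray  # (N,) bool
    per_network: "object"  # DataFrame: network, n_nodes, n_above, proportion, p_binomial


def flexibility_cutoff(
    ens: PartitionEnsemble,
    meta: NodeMetadata,
    node_ids,
    percentile: float = 95.0,
) -> FlexibilityCutoffReport:
    """Find networks overrepresented among highly flexible nodes.

    Flexibility is computed per node in every run; the cutoff is the
    given percentile of the pooled node-by-run values.  A node counts as
    highly flexible when its across-run mean flexibility exceeds the
    cutoff.  Each network's count is compared with the overall
    exceedance rate by a one-sided binomial test.
    """
    import pandas as pd

    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    flex = np.stack([node_flexibility(run) for run in ens])  # (R, N)
    pooled = flex.ravel()
    cutoff = float(np.percentile(pooled, percentile))
    node_mean = flex.mean(axis=0)
    exceeds = node_mean > cutoff
    overall_rate = exceeds.mean()
    rows = []
    for name, idx in meta.network_indices(node_ids).items():
        n_above = int(exceeds[idx].sum())
        size = len(idx)
        if size == 0:
            continue
        if overall_rate in (0.0, 1.0):
            p = 1.0 if n_above <= overall_rate * size else 0.0
        else:
            p = stats.binomtest(n_above, size, overall_rate, alternative="greater").pvalue
        rows.append(
            {
                "network": name,
                "n_nodes": size,
                "n_above": n_above,
                "proportion": n_above / size,
                "p_binomial": float(p),
            }
        )
    table = pd.DataFrame(rows).set_index("network")
    return FlexibilityCutoffReport(cutoff, percentile, node_mean, exceeds, table)
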