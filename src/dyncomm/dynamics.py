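"""Stability and reorganization measures on node-by-layer partitions.

Flexibility counts how often a node changes community label between
consecutive days, relative to the number of opportunities (L - 1);
persistence is the complementary fraction of unchanged node-transitions.
Reorganization events are coordinated label changes: a *split* is a
group of nodes leaving a shared community for a genuinely new label, a
*merge* is the disappearance of a label with all its members absorbed
into one existing community.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .network import MultilayerNetwork, NodeMetadata, Partition

__all__ = [
    "node_flexibility",
    "persistence",
    "sliding_window_flexibility",
    "composition_matrix",
    "hemispheric_symmetry",
    "edge_autocorrelation",
    "ReorganizationEvent",
    "detect_events",
    "edge_change_attribution",
]


def node_flexibility(part: Partition) -> np.ndarray:
    """Per-node fraction of adjacent-layer transitions with a label change.

    ``f_i = #{l : g_il != g_i,l+1} / (L - 1)``; 0 means the node never
    changes community, 1 means it changes at every opportunity.
    """
    g = part.labels
    if g.shape[1] < 2:
        raise ValueError("flexibility requires at least 2 layers")
    return (g[:, :-1] != g[:, 1:]).mean(axis=1)


def persistence(part: Partition) -> float:
    """Fraction of all (node, adjacent-layer) pairs with unchanged label.

    Equals ``1 - mean(node_flexibility)`` exactly (computed as the
    complement so the identity holds to the last bit).
    """
    g = part.labels
    if g.shape[1] < 2:
        raise ValueError("persistence requires at least 2 layers")
    return float(1.0 - node_flexibility(part).mean())


def sliding_window_flexibility(
    part: Partition,
    meta: NodeMetadata,
    node_ids,
    window: int = 5,
    align: str = "centered",
) -> pd.DataFrame:
    """Network-mean flexibility in a sliding window of days.

    Windows are centered by default, so a reorganization registers its
    flexibility peak on the days it actually spans (a day-22..24 event
    peaks at day 23).  With ``align="trailing"`` the value reported at
    day ``d`` summarizes transitions within days ``d - window + 1 .. d``.
    Positions where the window would leave the series are NaN.

    Returns a DataFrame indexed by network with one column per 1-based day.
    """
    g = part.labels
    N, L = g.shape
    if window < 2:
        raise ValueError("window must be >= 2")
    if window > L:
        raise ValueError(f"window ({window}) exceeds number of layers ({L})")
    if align not in ("trailing", "centered"):
        raise ValueError(f"unknown alignment {align!r}")
    changes = (g[:, :-1] != g[:, 1:]).astype(float)  # (N, L-1), transition t = day t+1 -> t+2
    net_idx = meta.network_indices(node_ids)
    days = np.arange(1, L + 1)
    out = pd.DataFrame(np.nan, index=sorted(net_idx), columns=days)
    for d in days:
        if align == "trailing":
            first_t, last_t = d - window, d - 2
        else:
            half = (window - 1) // 2
            first_t, last_t = d - 1 - half, d - 2 + (window - half - 1)
        if first_t < 0 or last_t > L - 2:
            continue
        win = changes[:, first_t : last_t + 1].mean(axis=1)  # per node, / (window-1)
        for name, idx in net_idx.items():
            if len(idx):
                out.loc[name, d] = win[idx].mean()
    return out


def composition_matrix(
    part: Partition, meta: NodeMetadata, node_ids
) -> tuple[pd.DataFrame, pd.Series]:
    """Community-by-network composition percentages and median daily sizes.

    Entry (c, n) is the percentage of (node, day) instances of community
    ``c`` whose node belongs to a priori network ``n``; rows sum to 100.
    The second return value is the median over days of each community's
    daily size (days where the community is absent are ignored).
    """
    g = part.labels
    N, L = g.shape
    nets = meta.networks.reindex(node_ids).to_numpy()
    net_names = meta.network_names()
    comms = sorted(int(c) for c in np.unique(g))
    comp = pd.DataFrame(0.0, index=comms, columns=net_names)
    for c in comms:
        node_counts = (g == c).sum(axis=1)  # instances per node
        for name in net_names:
            comp.loc[c, name] = node_counts[nets == name].sum()
    totals = comp.sum(axis=1)
    comp = comp.div(totals, axis=0) * 100.0
    sizes = pd.Series(
        {
            c: float(np.median([s for s in (g == c).sum(axis=0) if s > 0]))
            for c in comms
        },
        name="median_size",
    )
    return comp, sizes


def hemispheric_symmetry(part: Partition, meta: NodeMetadata, node_ids) -> float:
    """Fraction of (homolog pair, day) instances sharing a community label."""
    pairs = meta.homolog_pairs(node_ids)
    if not pairs:
        raise ValueError("no homolog pairs in metadata")
    g = part.labels
    agree = [g[i, :] == g[j, :] for i, j in pairs]
    return float(np.mean(agree))


def edge_autocorrelation(net: MultilayerNetwork, meta: NodeMetadata, network: str) -> float:
    """Day-to-day Pearson correlation of a network's internal edge weights.

    Pools every within-network node pair over all consecutive-day pairs
    (t, t+1) and correlates the day-t weights with the day-(t+1) weights.
    """
    if net.n_layers < 2:
        raise ValueError("need at least 2 layers")
    idx = meta.network_indices(net.node_ids).get(network)
    if idx is None or len(idx) < 2:
        raise ValueError(f"network {network!r} has fewer than 2 nodes")
    iu = np.triu_indices(len(idx), k=1)
    sub = net.A[np.ix_(idx, idx)]  # (n, n, L)
    w = sub[iu]  # (n_pairs, L)
    x = w[:, :-1].ravel()
    y = w[:, 1:].ravel()
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class ReorganizationEvent:
    """A coordinated community split or merge between consecutive days."""

    day: int  # 1-based layer at which the new labeling first applies
    kind: str  # "split" or "merge"
    node_set: tuple[int, ...]  # positional node indices
    source_community: int
    target_community: int
    duration: int  # consecutive days the (new) label persists; 1 for merges

    @property
    def size(self) -> int:
        return len(self.node_set)


def detect_events(part: Partition, min_size: int = 10) -> list[ReorganizationEvent]:
    """Find coordinated splits and merges of at least ``min_size`` nodes.

    A split at day ``l`` is a set of nodes that shared a label at
    ``l - 1`` and all carry a common label at ``l`` that did not exist at
    ``l - 1``; its duration counts the consecutive days the moved set
    remains separated from what is left of its source community (label
    bookkeeping can outlive the separation when the groups reunite, so
    label lifetime alone would overstate it).  A merge at day ``l`` is a
    label present at ``l - 1`` and
    absent at ``l`` whose members all move into one community that
    already existed at ``l - 1``.  Smaller or label-recycling moves
    contribute to flexibility but are not events.
    """
    g = part.labels
    N, L = g.shape
    events: list[ReorganizationEvent] = []
    for l in range(1, L):
        prev_labels = set(np.unique(g[:, l - 1]).tolist())
        cur_labels = set(np.unique(g[:, l]).tolist())
        for c in sorted(cur_labels - prev_labels):
            members = np.flatnonzero(g[:, l] == c)
            if len(members) < min_size:
                continue
            # the event set is the common-source subset of the new community
            for s in np.unique(g[members, l - 1]):
                moved = members[g[members, l - 1] == s]
                if len(moved) < min_size:
                    continue
                residual = np.flatnonzero(g[:, l - 1] == s)
                residual = np.setdiff1d(residual, moved)
                # duration = days the moved set stays apart from its source:
                # most movers still carry the new label while most of the
                # residual source does not (label bookkeeping may outlive
                # the separation when the groups reunite under either name)
                duration = 0
                for r in range(l, L):
                    movers_hold = np.mean(g[moved, r] == c) > 0.5
                    residual_joined = (
                        len(residual) > 0 and np.mean(g[residual, r] == c) > 0.5
                    )
                    if movers_hold and not residual_joined:
                        duration += 1
                    else:
                        break
                events.append(
                    ReorganizationEvent(
                        day=l + 1,
                        kind="split",
                        node_set=tuple(int(i) for i in moved),
                        source_community=int(s),
                        target_community=int(c),
                        duration=duration,
                    )
                )
        for c in sorted(prev_labels - cur_labels):
            members = np.flatnonzero(g[:, l - 1] == c)
            if len(members) < min_size:
                continue
            for t in np.unique(g[members, l]):
                if t not in prev_labels:
                    continue  # absorbed into an existing community only
                moved = members[g[members, l] == t]
                if len(moved) < min_size:
                    continue
                events.append(
                    ReorganizationEvent(
                        day=l + 1,
                        kind="merge",
                        node_set=tuple(int(i) for i in moved),
                        source_community=int(c),
                        target_community=int(t),
                        duration=1,
                    )
                )
    return events


def edge_change_attribution(
    net: MultilayerNetwork,
    meta: NodeMetadata,
    day: int,
    fraction: float = 0.05,
) -> dict:
    """Attribute the strongest day-to-day weight increases to network pairs.

    Ranks upper-triangle edges by the signed change
    ``A[:, :, day] - A[:, :, day - 1]`` (1-based ``day``; the change into
    that day) and keeps the top ``ceil(fraction * E)``; ties at the
    cutoff are broken toward the larger baseline weight.  Returns counts
    of selected edges per unordered (network, network) and
    (subnetwork, subnetwork) pair.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if not 2 <= day <= net.n_layers:
        raise ValueError(f"day must be in [2, {net.n_layers}]")
    t = day - 2  # 0-based baseline layer
    iu = np.triu_indices(net.n_nodes, k=1)
    delta = (net.A[:, :, t + 1] - net.A[:, :, t])[iu]
    baseline = net.A[:, :, t][iu]
    n_sel = ceil(fraction * delta.size)
    order = np.lexsort((-baseline, -delta))  # by delta desc, then baseline desc
    sel = order[:n_sel]
    degenerate = bool(np.all(delta[sel] == 0))
    nets = meta.networks.reindex(net.node_ids).to_numpy()
    subs = meta.table["subnetwork"].reindex(net.node_ids).to_numpy()

    def count_pairs(labels_arr):
        pairs = {}
        for e in sel:
            a, b = labels_arr[iu[0][e]], labels_arr[iu[1][e]]
            key = tuple(sorted((str(a), str(b))))
            pairs[key] = pairs.get(key, 0) + 1
        df = pd.Series(pairs, name="count").sort_values(ascending=False)
        df.index.names = ["group_i", "group_j"]
        return df.to_frame()

    return {
        "n_selected": int(n_sel),
        "degenerate": degenerate,
        "network_pairs": count_pairs(nets),
        "subnetwork_pairs": count_pairs(subs),
        "selected_edges": [(int(iu[0][e]), int(iu[1][e])) for e in sel],
    }
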