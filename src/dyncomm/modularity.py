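"""Multislice modularity and a seeded Louvain-type optimizer.

The optimizer works on the supra-modularity matrix ``B`` over the
``N * L`` (node, layer) slots:

* within layer ``l``:  ``B[(i,l),(j,l)] = A_ijl - gamma * k_il k_jl / (2 m_l)``
* between adjacent layers: ``B[(i,l),(i,l +/- 1)] = omega``

and maximizes ``Q = (1/2 mu) * sum_{u,v same community} B[u, v]``, the
diagonal null-model terms included.  Maximization alternates a
single-slot local-moving phase (randomized sweep order, ties broken
toward the lowest candidate label, moves accepted only for
``dQ > 1e-10``) with an aggregation phase in which whole communities are
moved as units; it stops when neither phase improves Q, so every
returned partition is single-move locally optimal.

A layer with zero total strength contributes no null-model term (all its
strengths vanish, so the ``k k / 2m`` limit is zero); in particular an
all-zero network with ``omega = 0`` has Q = 0 for every partition and
the optimizer returns the all-singleton partition.
"""

from __future__ import annotations

import numpy as np

from .network import (
    ModularityParams,
    MultilayerNetwork,
    Partition,
    PartitionEnsemble,
)

__all__ = [
    "multislice_modularity",
    "supra_modularity_matrix",
    "louvain_run",
    "run_ensemble",
    "parameter_sweep",
]

_MOVE_TOL = 1e-10


def multislice_modularity(
    net: MultilayerNetwork, part: Partition, params: ModularityParams | None = None
) -> float:
    """Evaluate the multislice quality function for a given partition.

    Computed directly from its definition: intralayer Newman-Girvan terms
    for every ordered (i, j) pair sharing a label within a layer
    (including i = j), plus ``omega`` for every ordered pair of adjacent
    layers in which a node keeps its label, normalized by
    ``2 mu = sum_l 2 m_l + 2 omega N (L - 1)``.
    """
    if params is None:
        params = part.params
    g = np.asarray(part.labels)
    if g.shape != (net.n_nodes, net.n_layers):
        raise ValueError(
            f"partition shape {g.shape} does not match network "
            f"({net.n_nodes}, {net.n_layers})"
        )
    k = net.strengths()
    totals = net.layer_totals()
    score = 0.0
    for l in range(net.n_layers):
        same = g[:, l][:, None] == g[:, l][None, :]
        intra = net.A[:, :, l].copy()
        if totals[l] > 0:
            intra -= params.gamma * np.outer(k[:, l], k[:, l]) / totals[l]
        score += intra[same].sum()
    if net.n_layers > 1:
        persistent = (g[:, :-1] == g[:, 1:]).sum()
        score += 2.0 * params.omega * persistent
    two_mu = net.two_mu(params.omega)
    if two_mu == 0:
        return 0.0
    return float(score / two_mu)


def supra_modularity_matrix(net: MultilayerNetwork, params: ModularityParams) -> np.ndarray:
    """Dense (N*L) x (N*L) supra-modularity matrix, slots ordered layer-major."""
    N, L = net.n_nodes, net.n_layers
    k = net.strengths()
    totals = net.layer_totals()
    B = np.zeros((N * L, N * L))
    for l in range(L):
        block = net.A[:, :, l].copy()
        if totals[l] > 0:
            block -= params.gamma * np.outer(k[:, l], k[:, l]) / totals[l]
        B[l * N : (l + 1) * N, l * N : (l + 1) * N] = block
    idx = np.arange(N)
    for l in range(L - 1):
        B[l * N + idx, (l + 1) * N + idx] = params.omega
        B[(l + 1) * N + idx, l * N + idx] = params.omega
    return B


def _contiguous(labels: np.ndarray) -> np.ndarray:
    _, inv = np.unique(labels, return_inverse=True)
    return inv


def _sweep_py(B: np.ndarray, labels: np.ndarray, order: np.ndarray, n_lab: int) -> int:
    """One relocation pass in the given node order; mutates labels."""
    moved = 0
    for v in order:
        cur = labels[v]
        w = np.bincount(labels, weights=B[v], minlength=n_lab)
        base = w[cur] - B[v, v]
        gains = w - base
        gains[cur] = 0.0
        best = int(np.argmax(gains))  # first max -> lowest label
        best_gain = gains[best]
        # a fresh singleton community has gain -base
        if -base > best_gain + _MOVE_TOL:
            best, best_gain = n_lab, -base
        if best_gain > _MOVE_TOL and best != cur:
            labels[v] = best
            if best == n_lab:
                n_lab += 1
            moved += 1
    return moved


try:  # compiled sweep; semantics identical to _sweep_py
    from numba import njit

    @njit(cache=False)
    def _sweep_nb(B, labels, order, n_lab):  # pragma: no cover - mirrors _sweep_py
        n = B.shape[0]
        moved = 0
        w = np.zeros(2 * n + 1)
        for oi in range(n):
            v = order[oi]
            cur = labels[v]
            for c in range(n_lab + 1):
                w[c] = 0.0
            for u in range(n):
                w[labels[u]] += B[v, u]
            base = w[cur] - B[v, v]
            best = 0
            best_gain = 0.0 if cur == 0 else w[0] - base
            for c in range(1, n_lab):
                g = 0.0 if c == cur else w[c] - base
                if g > best_gain:
                    best, best_gain = c, g
            if -base > best_gain + _MOVE_TOL:
                best, best_gain = n_lab, -base
            if best_gain > _MOVE_TOL and best != cur:
                labels[v] = best
                if best == n_lab:
                    n_lab += 1
                moved += 1
        return moved

    _sweep = _sweep_nb
except ImportError:  # pragma: no cover
    _sweep = _sweep_py


def _local_move(B: np.ndarray, labels: np.ndarray, rng: np.random.Generator) -> bool:
    """Greedy single-slot relocation sweeps until no move improves Q.

    Labels are compressed to contiguous integers before each pass (this
    preserves their relative order, hence the lowest-label tie rule).
    Mutates ``labels`` in place; returns whether anything moved.
    """
    n = B.shape[0]
    improved = False
    while True:
        labels[:] = _contiguous(labels)
        order = rng.permutation(n)
        moved = int(_sweep(B, labels, order, int(labels.max()) + 1))
        if moved == 0:
            break
        improved = True
    return improved


def _aggregate(B: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Community-by-community sums of B (grouped two-sided reduction)."""
    idx = np.argsort(labels, kind="stable")
    starts = np.flatnonzero(np.r_[1, np.diff(labels[idx])])
    cols = np.add.reduceat(B[:, idx], starts, axis=1)
    return np.add.reduceat(cols[idx], starts, axis=0)


def louvain_run(
    net: MultilayerNetwork,
    params: ModularityParams | None = None,
    seed: int = 0,
    _supra: np.ndarray | None = None,
) -> Partition:
    """One seeded Louvain-type maximization of multislice modularity.

    Deterministic given ``seed``.  The returned partition carries
    canonicalized labels and the achieved Q.  ``_supra`` lets callers
    reuse a precomputed supra-modularity matrix across runs.
    """
    if params is None:
        params = ModularityParams()
    rng = np.random.default_rng(seed)
    B = supra_modularity_matrix(net, params) if _supra is None else _supra
    n = B.shape[0]
    labels = np.arange(n)
    while True:
        _local_move(B, labels, rng)
        labels = _contiguous(labels)
        C = _aggregate(B, labels)
        agg = np.arange(C.shape[0])
        if not _local_move(C, agg, rng):
            break
        labels = _contiguous(agg)[labels]
    part = Partition(
        labels.reshape(net.n_layers, net.n_nodes).T, params=params, seed=seed
    ).canonicalized()
    part.quality = multislice_modularity(net, part, params)
    return part


def run_ensemble(
    net: MultilayerNetwork,
    params: ModularityParams | None = None,
    n_runs: int = 150,
    base_seed: int = 0,
) -> PartitionEnsemble:
    """``n_runs`` independent optimizations with seeds base_seed..base_seed+R-1."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if params is None:
        params = ModularityParams()
    B = supra_modularity_matrix(net, params)
    return PartitionEnsemble(
        [louvain_run(net, params, seed=base_seed + r, _supra=B) for r in range(n_runs)]
    )


def parameter_sweep(
    net: MultilayerNetwork,
    gamma_grid,
    omega_grid,
    n_runs: int = 150,
    base_seed: int = 0,
    n_null_draws: int = 200,
    alpha: float = 0.05,
):
    """Ensemble + consensus + community significance per (gamma, omega) cell.

    Returns a list of dicts with keys gamma, omega, ensemble, consensus,
    n_communities, fraction_significant; grid order is row-major over
    (gamma, omega).
    """
    from .consensus import community_significance, consensus_partition

    gamma_grid = list(gamma_grid)
    omega_grid = list(omega_grid)
    if not gamma_grid or not omega_grid:
        raise ValueError("parameter grids must be nonempty")
    cells = []
    for gi, gamma in enumerate(gamma_grid):
        for oi, omega in enumerate(omega_grid):
            params = ModularityParams(gamma=gamma, omega=omega)
            cell_seed = base_seed + 10_000 * (gi * len(omega_grid) + oi)
            ens = run_ensemble(net, params, n_runs=n_runs, base_seed=cell_seed)
            cons = consensus_partition(ens)
            report = community_significance(
                net, cons.partition, n_draws=n_null_draws, alpha=alpha,
                seed=cell_seed + 1,
            )
            frac = float(np.mean([report.significant[c] for c in report.communities]))
            cells.append(
                {
                    "gamma": gamma,
                    "omega": omega,
                    "ensemble": ens,
                    "consensus": cons,
                    "n_communities": cons.partition.n_communities(),
                    "fraction_significant": frac,
                }
            )
    return cells
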