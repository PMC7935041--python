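"""Relating network flexibility to cycle phase and hormone levels.

Phase comparisons use node-level flexibility restricted to each phase's
own day-to-day transitions (a transition into day ``d`` belongs to the
phase of day ``d``), compared pairwise across nodes with two-sided
Wilcoxon rank-sum tests.  Hormone coupling uses Spearman rank
correlation between each network's sliding-window flexibility series
and each hormone's daily series, Bonferroni-corrected over the full
network-by-hormone family.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .network import Partition

__all__ = [
    "HORMONES",
    "phase_flexibility_comparison",
    "hormone_flexibility_correlation",
    "cross_covariance",
]

HORMONES = ("estradiol", "progesterone", "testosterone", "lh", "fsh")


def _validate_phase_map(phase_map: dict[int, str], n_layers: int) -> None:
    days = sorted(phase_map)
    if days != list(range(1, n_layers + 1)):
        raise ValueError("phase map must label every day 1..L exactly once")


def phase_flexibility_comparison(
    part: Partition, phase_map: dict[int, str]
) -> dict:
    """Per-phase mean node flexibility and pairwise rank-sum p-values.

    Each node's flexibility within a phase counts only label changes on
    that phase's transitions; the transition from day ``d`` to ``d + 1``
    is attributed to the phase of day ``d + 1``, so a boundary change is
    never counted twice.  Phases are compared across nodes with a
    two-sided Wilcoxon rank-sum (Mann-Whitney) test, exact for small
    tie-free samples and normal-approximated with tie correction
    otherwise.
    """
    g = part.labels
    N, L = g.shape
    _validate_phase_map(phase_map, L)
    changes = g[:, :-1] != g[:, 1:]  # transition t: day t+1 -> t+2
    phases = sorted(set(phase_map.values()))
    per_phase: dict[str, np.ndarray] = {}
    for ph in phases:
        trans = [t for t in range(L - 1) if phase_map[t + 2] == ph]
        if not trans:
            raise ValueError(f"phase {ph!r} contains no transitions (fewer than 2 days)")
        per_phase[ph] = changes[:, trans].mean(axis=1)
    means = {ph: float(v.mean()) for ph, v in per_phase.items()}
    pvals: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(phases, 2):
        res = stats.mannwhitneyu(
            per_phase[a], per_phase[b], alternative="two-sided", method="auto"
        )
        pvals[(a, b)] = float(res.pvalue)
    return {"mean_flexibility": means, "node_flexibility": per_phase, "p_values": pvals}


def _spearman(x: np.ndarray, y: np.ndarray, method: str, rng, n_perm: int):
    """Spearman rho with either a permutation or asymptotic-t p-value.

    The t approximation is anti-conservative in the far tail (precisely
    where Bonferroni thresholds land), so the default is a permutation
    null: rho is recomputed for ``n_perm`` random reorderings of one
    series and ``p = (1 + #{|null| >= |obs|}) / (n_perm + 1)``, valid
    under exchangeability by construction.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        return np.nan, np.nan
    rho = float(rxc @ ryc / denom)
    if method == "asymptotic":
        return rho, float(stats.spearmanr(x, y).pvalue)
    idx = rng.random((n_perm, len(x))).argsort(axis=1)
    null = ryc[idx] @ rxc / denom
    p = (1 + int(np.sum(np.abs(null) >= abs(rho) - 1e-12))) / (n_perm + 1)
    return rho, float(p)


def hormone_flexibility_correlation(
    window_flex: pd.DataFrame,
    hormones: pd.DataFrame,
    alpha: float = 0.05,
    family: int | None = None,
    rho_threshold: float = 0.6,
    method: str = "permutation",
    n_perm: int = 2000,
) -> pd.DataFrame:
    """Spearman correlation of each network's flexibility with each hormone.

    ``window_flex`` is a network-by-day matrix (NaN where the sliding
    window is incomplete); ``hormones`` a day-indexed panel with the
    standard hormone columns.  Days missing from either series are
    dropped pairwise; a constant series yields a missing correlation.
    Bonferroni correction uses ``family`` tests (default: number of
    networks times number of hormones).  A row "passes" when rho exceeds
    ``rho_threshold`` and survives correction.  P-values come from a
    seeded permutation null by default (``method="asymptotic"`` restores
    the t approximation); results are deterministic.
    """
    if method not in ("permutation", "asymptotic"):
        raise ValueError(f"unknown p-value method {method!r}")
    perm_rng = np.random.default_rng(181711)
    horm = hormones.set_index("day") if "day" in hormones.columns else hormones
    horm_cols = [h for h in HORMONES if h in horm.columns]
    if not horm_cols:
        raise ValueError("hormone panel has no recognized hormone columns")
    networks = list(window_flex.index)
    if family is None:
        family = len(networks) * len(horm_cols)
    rows = []
    for net in networks:
        flex = window_flex.loc[net]
        flex.index = flex.index.astype(int)
        for h in horm_cols:
            joint = pd.concat([flex, horm[h]], axis=1, join="inner").dropna()
            if len(joint) < 5:
                raise ValueError("need at least 5 complete days per correlation")
            x, y = joint.iloc[:, 0].to_numpy(), joint.iloc[:, 1].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho, p = np.nan, np.nan
            else:
                rho, p = _spearman(x, y, method, perm_rng, n_perm)
            p_bonf = min(1.0, p * family) if np.isfinite(p) else np.nan
            sig = bool(np.isfinite(p_bonf) and p_bonf < alpha)
            rows.append(
                {
                    "network": net,
                    "hormone": h,
                    "rho": rho,
                    "p": p,
                    "p_bonferroni": p_bonf,
                    "significant": sig,
                    "passes": bool(sig and np.isfinite(rho) and rho > rho_threshold),
                    "n_days": len(joint),
                }
            )
    return pd.DataFrame(rows)


def cross_covariance(x, y, max_lag: int) -> pd.Series:
    """Mean-removed cross-covariance at lags -max_lag..max_lag.

    ``c(k) = (1/n) * sum_t (x_t - mean(x)) * (y_{t+k} - mean(y))`` over
    the overlapping samples, so lag 0 equals the (1/n-normalized) sample
    covariance and a copy of ``x`` delayed by ``k`` peaks at lag ``k``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    n = x.size
    if n < max_lag + 2:
        raise ValueError("series too short for requested max_lag")
    xc = x - x.mean()
    yc = y - y.mean()
    lags = np.arange(-max_lag, max_lag + 1)
    vals = []
    for k in lags:
        if k >= 0:
            vals.append(np.dot(xc[: n - k], yc[k:]) / n)
        else:
            vals.append(np.dot(xc[-k:], yc[: n + k]) / n)
    return pd.Series(vals, index=lags, name="cross_covariance")
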