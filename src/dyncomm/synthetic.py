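"""Synthetic multilayer scenarios with planted community structure.

The generator emulates a dense-sampling resting-state experiment: one
weighted association matrix per day for 30 consecutive days, a handful
of stable community "cores" aligned with a priori functional networks,
and a scripted transient reorganization in which a sub-block of one core
strengthens internally and splits off for a few days around a hormonal
(ovulatory) peak, plus a smaller earlier event reusing most of the same
nodes.  A "suppressed" variant (hormonal-regimen analogue) plants no
events and flattens the gonadotropin curves.

Edge weights are Beta-distributed on (0, 1) — the natural support for
coherence-like association values — parameterized by a mean and a
concentration, with higher means inside cores than between them.
Hormone curves are baseline plus Gaussian bumps with multiplicative
log-normal noise; no attempt is made to model endocrine
pharmacokinetics beyond the timing of the peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import MultilayerNetwork, NodeMetadata, Partition

__all__ = [
    "ScenarioConfig",
    "generate_multilayer",
    "generate_timeseries",
    "generate_hormones",
    "default_phase_map",
    "CORE_NETWORK_NAMES",
]

CORE_NETWORK_NAMES = (
    "visual",
    "default_mode",
    "control",
    "somatomotor",
    "limbic",
    "subcortical",
    "dorsal_attention",
    "salience_ventral_attention",
    "temporoparietal",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one planted scenario.

    The defaults describe the standard test scenario: 60 nodes in 4
    cores (the default-mode-like core twice the size of the others)
    over 30 days, with a 10-node sub-block of the default-mode core
    splitting off on days 22-24 and a secondary event on days 8-10
    reusing 90% of the same nodes.  During event days the block's
    internal Beta mean rises by ``split_boost`` and its links to the
    rest of its core drop by ``split_detach``.
    """

    n_nodes: int = 60
    n_layers: int = 30
    n_cores: int = 4
    core_assignment: tuple[int, ...] | None = None  # node -> core; default equal blocks
    weight_within_mean: float = 0.45
    weight_between_mean: float = 0.25
    weight_concentration: float = 40.0
    split_members: tuple[int, ...] | None = None  # default: first 10 nodes of core 1
    split_days: tuple[int, int] | None = None  # default: (22, 24) at L = 30
    split_boost: float = 0.3
    split_detach: float = 0.2
    secondary_event_days: tuple[int, int] | None = "auto"  # default: (8, 10) at L = 30
    secondary_reuse_fraction: float = 0.9
    suppressed: bool = False
    seed: int = 0

    # -- derived views ------------------------------------------------------
    def cores(self) -> np.ndarray:
        """Node -> core index, length n_nodes.

        By default, four cores get size fractions (0.2, 0.4, 0.2, 0.2):
        the second ("default mode") core is the largest, so its transient
        split block stays smaller than the remaining core — the side that
        must adopt the new community label.  Other core counts split
        nodes equally.
        """
        if self.core_assignment is not None:
            cores = np.asarray(self.core_assignment, dtype=int)
            if cores.shape != (self.n_nodes,):
                raise ValueError("core_assignment length must equal n_nodes")
            if set(np.unique(cores)) != set(range(self.n_cores)):
                raise ValueError("core_assignment must use cores 0..n_cores-1")
            return cores
        if self.n_cores == 4:
            fractions = np.array([0.2, 0.4, 0.2, 0.2])
        else:
            fractions = np.full(self.n_cores, 1.0 / self.n_cores)
        bounds = np.round(np.cumsum(fractions) * self.n_nodes).astype(int)
        return np.searchsorted(bounds, np.arange(self.n_nodes), side="right")

    def split_nodes(self) -> np.ndarray:
        """Default: the leading ~40% of the largest ("default mode") core."""
        if self.split_members is not None:
            return np.asarray(self.split_members, dtype=int)
        cores = self.cores()
        core1 = np.flatnonzero(cores == 1 % self.n_cores)
        k = max(2, int(round(0.4 * len(core1))))
        return core1[:k]

    def secondary_nodes(self) -> np.ndarray:
        """The earlier event reuses a leading fraction of the split block."""
        members = self.split_nodes()
        k = max(2, int(round(self.secondary_reuse_fraction * len(members))))
        return members[:k]

    def resolved_split_days(self) -> tuple[int, int] | None:
        """Primary event window; defaults to ~3 days around 0.73 L (22-24 at L=30)."""
        if self.split_days is not None:
            return self.split_days
        L = self.n_layers
        if L < 8:
            return None  # too short to host a transient event
        lo = max(2, int(round(0.72 * L)))
        return lo, min(L, lo + 2)

    def resolved_secondary_days(self) -> tuple[int, int] | None:
        """Secondary event window; defaults to ~3 days around 0.3 L (8-10 at L=30)."""
        if self.secondary_event_days != "auto":
            return self.secondary_event_days
        primary = self.resolved_split_days()
        if primary is None:
            return None
        lo = max(2, int(round(0.27 * self.n_layers)))
        hi = lo + 2
        if hi >= primary[0] - 1:
            return None  # would touch the primary window
        return lo, hi

    def validate(self) -> None:
        if self.n_nodes < 2 or self.n_layers < 1 or self.n_cores < 1:
            raise ValueError("n_nodes, n_layers and n_cores must be positive")
        for m in (self.weight_within_mean, self.weight_between_mean):
            if not 0 < m < 1:
                raise ValueError("weight means must lie in (0, 1)")
        if not 0 < self.weight_within_mean + self.split_boost < 1:
            raise ValueError("boosted within-split mean must stay in (0, 1)")
        if self.split_detach < 0 or self.weight_within_mean - self.split_detach <= 0:
            raise ValueError("detached block-core mean must stay in (0, 1)")
        if self.weight_concentration <= 0:
            raise ValueError("weight_concentration must be positive")
        split = self.resolved_split_days()
        if split is not None:
            lo, hi = split
            if not (1 <= lo <= hi <= self.n_layers):
                raise ValueError("split_days must lie within [1, n_layers]")
        secondary = self.resolved_secondary_days()
        if secondary is not None:
            lo, hi = secondary
            if not (1 <= lo <= hi <= self.n_layers):
                raise ValueError("secondary_event_days must lie within [1, n_layers]")
        cores = self.cores()
        members = self.split_nodes()
        if len(set(cores[members])) != 1:
            raise ValueError("split_members must belong to a single core")
        if len(members) >= np.sum(cores == cores[members[0]]):
            raise ValueError("split_members must be a proper subset of their core")


def _core_network_name(core: int) -> str:
    if core < len(CORE_NETWORK_NAMES):
        return CORE_NETWORK_NAMES[core]
    return f"network_{core}"


def _build_metadata(config: ScenarioConfig) -> NodeMetadata:
    cores = config.cores()
    split = set(int(i) for i in config.split_nodes())
    rows = []
    # pair consecutive same-core nodes as left/right homologs
    homolog = {}
    for core in range(config.n_cores):
        members = np.flatnonzero(cores == core)
        for a, b in zip(members[0::2], members[1::2]):
            homolog[int(a)] = int(b)
            homolog[int(b)] = int(a)
    for i in range(config.n_nodes):
        net = _core_network_name(int(cores[i]))
        sub = f"{net}_B" if i in split else f"{net}_A"
        if i in homolog:
            hemi = "L" if i < homolog[i] else "R"
            hom: object = f"n{homolog[i]:03d}"
        else:
            hemi, hom = "NA", np.nan
        rows.append(
            {
                "node_id": f"n{i:03d}",
                "name": f"{net}_{i:03d}",
                "network": net,
                "subnetwork": sub,
                "hemisphere": hemi,
                "homolog_id": hom,
            }
        )
    return NodeMetadata(pd.DataFrame(rows))


def _event_days(config: ScenarioConfig) -> tuple[set[int], set[int]]:
    """(split event days, secondary event days), empty when suppressed."""
    if config.suppressed:
        return set(), set()
    primary = config.resolved_split_days()
    split_days = set(range(primary[0], primary[1] + 1)) if primary else set()
    secondary: set[int] = set()
    sec = config.resolved_secondary_days()
    if sec is not None:
        secondary = set(range(sec[0], sec[1] + 1)) - split_days
    return split_days, secondary


def ground_truth_partition(config: ScenarioConfig) -> Partition:
    """Planted node-by-layer labels: cores everywhere, event label during events."""
    cores = config.cores()
    labels = np.tile(cores[:, None], (1, config.n_layers))
    split_days, secondary_days = _event_days(config)
    new_label = config.n_cores
    for day in split_days:
        labels[config.split_nodes(), day - 1] = new_label
    for day in secondary_days:
        labels[config.secondary_nodes(), day - 1] = new_label
    return Partition(labels)


def generate_multilayer(
    config: ScenarioConfig | None = None,
) -> tuple[MultilayerNetwork, Partition, NodeMetadata]:
    """Draw a multilayer network with planted cores and scripted events.

    Every layer is symmetric with zero diagonal and weights strictly in
    (0, 1).  During event days the within-event-block Beta mean is
    raised by ``split_boost``; the ground-truth partition labels the
    event block as its own community on exactly those days.
    """
    if config is None:
        config = ScenarioConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    cores = config.cores()
    N, L = config.n_nodes, config.n_layers
    same_core = cores[:, None] == cores[None, :]
    base_mean = np.where(same_core, config.weight_within_mean, config.weight_between_mean)
    split_days, secondary_days = _event_days(config)

    def event_masks(members: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        within = np.zeros((N, N), dtype=bool)
        within[np.ix_(members, members)] = True
        rest = np.setdiff1d(np.flatnonzero(cores == cores[members[0]]), members)
        cross = np.zeros((N, N), dtype=bool)
        cross[np.ix_(members, rest)] = True
        cross |= cross.T
        return within, cross

    split_within, split_cross = event_masks(config.split_nodes())
    sec_within, sec_cross = event_masks(config.secondary_nodes())
    conc = config.weight_concentration
    layers = np.zeros((N, N, L))
    iu = np.triu_indices(N, k=1)
    for l in range(L):
        day = l + 1
        mean = base_mean.copy()
        if day in split_days:
            mean = np.where(split_within, mean + config.split_boost, mean)
            mean = np.where(split_cross, mean - config.split_detach, mean)
        elif day in secondary_days:
            mean = np.where(sec_within, mean + config.split_boost, mean)
            mean = np.where(sec_cross, mean - config.split_detach, mean)
        a = mean[iu] * conc
        b = (1.0 - mean[iu]) * conc
        w = rng.beta(a, b)
        layer = np.zeros((N, N))
        layer[iu] = w
        layers[:, :, l] = layer + layer.T
    net = MultilayerNetwork(
        layers,
        node_ids=[f"n{i:03d}" for i in range(N)],
        layer_days=list(range(1, L + 1)),
    )
    return net, ground_truth_partition(config), _build_metadata(config)


def generate_timeseries(
    config: ScenarioConfig | None = None,
    samples_per_day: int = 512,
    snr: float = 2.0,
    sampling_interval: float = 0.72,
):
    """Per-day node-by-time series whose coherence reflects the planted labels.

    Each community in each layer gets an independent band-limited
    (0.01-0.17 Hz) latent signal; a node's series is its community's
    latent plus independent white noise, with ``snr`` the latent/noise
    standard-deviation ratio.  Returns ``(series_list, ground_truth,
    metadata)`` where ``series_list`` holds one
    :class:`~dyncomm.connectivity.RoiTimeSeriesSet` per day.
    """
    from scipy.signal import butter, filtfilt

    from .connectivity import RoiTimeSeriesSet

    if config is None:
        config = ScenarioConfig()
    config.validate()
    if samples_per_day < 64:
        raise ValueError("samples_per_day must be >= 64")
    if snr <= 0:
        raise ValueError(f"snr must be positive, got {snr}")
    rng = np.random.default_rng(config.seed + 1_000_003)
    truth = ground_truth_partition(config)
    meta = _build_metadata(config)
    fs = 1.0 / sampling_interval
    b_coef, a_coef = butter(4, [0.01, 0.17], btype="bandpass", fs=fs)
    T = samples_per_day
    out = []
    for l in range(config.n_layers):
        labels = truth.labels[:, l]
        latents = {}
        for c in np.unique(labels):
            raw = rng.standard_normal(T + 256)
            band = filtfilt(b_coef, a_coef, raw)[256:]
            latents[c] = band / band.std()
        noise = rng.standard_normal((config.n_nodes, T)) / snr
        data = np.stack([latents[c] for c in labels]) + noise
        out.append(
            RoiTimeSeriesSet(
                day=l + 1,
                data=data,
                sampling_interval=sampling_interval,
                node_ids=[f"n{i:03d}" for i in range(config.n_nodes)],
            )
        )
    return out, truth, meta


def default_phase_map(n_layers: int = 30) -> dict[int, str]:
    """Cycle-phase label per day: follicular 11-22, ovulatory 23-25, luteal rest."""
    phases = {}
    for day in range(1, n_layers + 1):
        if 11 <= day <= 22:
            phases[day] = "follicular"
        elif 23 <= day <= 25:
            phases[day] = "ovulatory"
        else:
            phases[day] = "luteal"
    return phases


def _bump(days: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((days - center) / width) ** 2)


def generate_hormones(config: ScenarioConfig | None = None) -> pd.DataFrame:
    """Daily serum hormone panel coupled to the planted events.

    Estradiol (pg/mL) peaks at the centre of the split window with a
    smaller secondary peak at the earlier event; LH and FSH (IU/L) spike
    only at the primary peak; progesterone (ng/mL) rises in the late
    luteal days.  The suppressed scenario keeps estradiol levels
    comparable but moves its (smaller) peak away from any event, flattens
    LH/FSH to baseline noise, and cuts progesterone by 97%.
    """
    if config is None:
        config = ScenarioConfig()
    config.validate()
    rng = np.random.default_rng(config.seed + 2_000_003)
    L = config.n_layers
    days = np.arange(1, L + 1, dtype=float)
    split = config.resolved_split_days()
    primary = 0.5 * (split[0] + split[1]) if split else 0.75 * L
    sec = config.resolved_secondary_days()
    secondary = 0.5 * (sec[0] + sec[1]) if sec else None
    if not config.suppressed:
        estradiol = 50.0 + 220.0 * _bump(days, primary, 1.3)
        if secondary is not None:
            estradiol += 90.0 * _bump(days, secondary, 1.6)
        lh = 4.0 + 45.0 * _bump(days, primary, 0.8)
        fsh = 5.0 + 14.0 * _bump(days, primary, 1.0)
        progesterone = 0.5 + 9.0 * _bump(days, min(primary + 5.0, L), 2.5)
    else:
        estradiol = 50.0 + 120.0 * _bump(days, 15.0, 4.0)
        lh = np.full(L, 4.0)
        fsh = np.full(L, 5.0)
        progesterone = 0.03 * (0.5 + 9.0 * _bump(days, min(primary + 5.0, L), 2.5))
    testosterone = np.full(L, 30.0)
    noise = lambda: np.exp(0.08 * rng.standard_normal(L))  # noqa: E731
    phase_map = default_phase_map(L)
    panel = pd.DataFrame(
        {
            "day": days.astype(int),
            "estradiol": estradiol * noise(),
            "progesterone": progesterone * noise(),
            "testosterone": testosterone * noise(),
            "lh": lh * noise(),
            "fsh": fsh * noise(),
        }
    )
    panel["phase"] = [phase_map[d] for d in panel["day"]]
    return panel
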