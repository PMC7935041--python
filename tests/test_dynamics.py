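"""Flexibility, persistence, composition, symmetry, events, attribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dyncomm as dc


def part(labels):
    return dc.Partition(np.asarray(labels))


def make_meta(networks, subnetworks=None, homologs=None):
    n = len(networks)
    subnetworks = subnetworks or [f"{net}_A" for net in networks]
    rows = []
    for i in range(n):
        hom = np.nan
        if homologs and i in homologs:
            hom = f"n{homologs[i]}"
        rows.append({"node_id": f"n{i}", "name": f"n{i}", "network": networks[i],
                     "subnetwork": subnetworks[i],
                     "hemisphere": "NA" if pd.isna(hom) else ("L" if i < homologs[i] else "R"),
                     "homolog_id": hom})
    return dc.NodeMetadata(pd.DataFrame(rows))


class TestFlexibilityAndPersistence:
    def test_textbook_values(self):
        assert dc.node_flexibility(part(np.zeros((3, 30))))  .tolist() == [0, 0, 0]
        alternating = np.tile([0, 1], (2, 15))
        assert dc.node_flexibility(part(alternating)).tolist() == [1, 1]
        assert dc.node_flexibility(part([[1, 1, 2, 2]]))[0] == pytest.approx(1 / 3)

    def test_persistence_limits(self):
        assert dc.persistence(part(np.zeros((4, 10)))) == 1.0
        assert dc.persistence(part(np.tile([0, 1], (4, 5)))) == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mean_flexibility_plus_persistence_is_one(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 5, size=(rng.integers(2, 10), rng.integers(2, 12)))
        p = part(labels)
        assert dc.node_flexibility(p).mean() + dc.persistence(p) == pytest.approx(1.0)

    def test_relabeling_invariance(self, rng):
        labels = rng.integers(0, 4, size=(6, 8))
        perm = rng.permutation(8)
        assert np.array_equal(dc.node_flexibility(part(labels)),
                              dc.node_flexibility(part(perm[labels])))

    def test_single_layer_rejected(self):
        with pytest.raises(ValueError):
            dc.node_flexibility(part(np.zeros((3, 1))))
        with pytest.raises(ValueError):
            dc.persistence(part(np.zeros((3, 1))))


class TestSlidingWindow:
    def test_constant_partition_all_zero(self):
        meta = make_meta(["a"] * 4)
        wf = dc.sliding_window_flexibility(part(np.zeros((4, 10))), meta,
                                           [f"n{i}" for i in range(4)], window=3)
        assert np.nanmax(wf.to_numpy()) == 0.0

    def test_event_localized_in_windows_covering_it(self):
        labels = np.zeros((4, 30), dtype=int)
        labels[:, 21:24] = 1  # days 22-24 distinct
        meta = make_meta(["a"] * 4)
        wf = dc.sliding_window_flexibility(part(labels), meta,
                                           [f"n{i}" for i in range(4)],
                                           window=5, align="centered")
        vals = wf.loc["a"]
        assert vals.idxmax() in (22, 23, 24)
        # windows disjoint from the event days are zero
        assert vals.loc[3:18].max() == 0.0
        assert vals.loc[29:].fillna(0).max() == 0.0

    def test_trailing_full_window_recovers_whole_series_mean(self, rng):
        labels = rng.integers(0, 3, size=(5, 12))
        meta = make_meta(["a"] * 5)
        wf = dc.sliding_window_flexibility(part(labels), meta,
                                           [f"n{i}" for i in range(5)],
                                           window=12, align="trailing")
        assert wf.loc["a", 12] == pytest.approx(
            dc.node_flexibility(part(labels)).mean())
        assert wf.loc["a", :11].isna().all()

    def test_oversized_window_rejected(self):
        meta = make_meta(["a"] * 3)
        with pytest.raises(ValueError, match="window"):
            dc.sliding_window_flexibility(part(np.zeros((3, 5))), meta,
                                          ["n0", "n1", "n2"], window=6)


class TestCompositionAndSymmetry:
    def test_composition_percentages(self):
        labels = np.zeros((10, 4), dtype=int)
        meta = make_meta(["visual"] * 8 + ["limbic"] * 2)
        comp, sizes = dc.composition_matrix(part(labels), meta,
                                            [f"n{i}" for i in range(10)])
        assert comp.loc[0, "visual"] == pytest.approx(80.0)
        assert comp.loc[0, "limbic"] == pytest.approx(20.0)
        assert comp.sum(axis=1).tolist() == pytest.approx([100.0])
        assert sizes[0] == 10.0

    def test_single_network_community_is_pure(self):
        labels = np.array([[0, 0], [0, 0], [1, 1]])
        meta = make_meta(["a", "a", "b"])
        comp, _ = dc.composition_matrix(part(labels), meta, ["n0", "n1", "n2"])
        assert comp.loc[0, "a"] == 100.0
        assert comp.loc[1, "b"] == 100.0

    def test_planted_scenario_composition_diagonal(self, default_scenario):
        _, net, truth, meta = default_scenario
        comp, _ = dc.composition_matrix(truth, meta, net.node_ids)
        # each core community is drawn from exactly one network
        for c in range(4):
            assert comp.loc[c].max() == pytest.approx(100.0)

    def test_hemispheric_symmetry_values(self):
        homologs = {0: 1, 1: 0, 2: 3, 3: 2}
        meta = make_meta(["a"] * 4, homologs=homologs)
        ids = [f"n{i}" for i in range(4)]
        mirrored = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
        assert dc.hemispheric_symmetry(part(mirrored), meta, ids) == 1.0
        half = np.array([[0, 0], [0, 0], [1, 1], [2, 2]])
        assert dc.hemispheric_symmetry(part(half), meta, ids) == 0.5
        disjoint = np.array([[0, 0], [1, 1], [2, 2], [3, 3]])
        assert dc.hemispheric_symmetry(part(disjoint), meta, ids) == 0.0

    def test_no_homologs_rejected(self):
        meta = make_meta(["a", "a"])
        with pytest.raises(ValueError, match="homolog"):
            dc.hemispheric_symmetry(part(np.zeros((2, 2))), meta, ["n0", "n1"])


class TestEdgeAutocorrelation:
    def ids(self, n):
        return [f"n{i}" for i in range(n)]

    def test_static_layers_fully_correlated(self, rng):
        M = rng.uniform(0.2, 0.8, (6, 6))
        M = 0.5 * (M + M.T)
        np.fill_diagonal(M, 0)
        net = dc.MultilayerNetwork(np.repeat(M[:, :, None], 5, axis=2),
                                   node_ids=self.ids(6))
        meta = make_meta(["a"] * 6)
        assert dc.edge_autocorrelation(net, meta, "a") == pytest.approx(1.0)

    def test_independent_layers_uncorrelated(self, rng):
        A = rng.uniform(0.1, 0.9, (40, 40, 30))
        A = 0.5 * (A + A.transpose(1, 0, 2))
        for l in range(30):
            np.fill_diagonal(A[:, :, l], 0)
        net = dc.MultilayerNetwork(A, node_ids=self.ids(40))
        meta = make_meta(["a"] * 40)
        assert abs(dc.edge_autocorrelation(net, meta, "a")) < 0.05

    def test_ar1_edges_recover_rho(self, rng):
        rho = 0.5
        n, L = 30, 40
        iu = np.triu_indices(n, k=1)
        E = len(iu[0])
        x = np.zeros((E, L))
        x[:, 0] = rng.standard_normal(E)
        for t in range(1, L):
            x[:, t] = rho * x[:, t - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(E)
        A = np.zeros((n, n, L))
        for l in range(L):
            M = np.zeros((n, n))
            M[iu] = 0.5 + 0.1 * x[:, l]
            A[:, :, l] = np.abs(M + M.T)
        net = dc.MultilayerNetwork(A, node_ids=self.ids(n))
        meta = make_meta(["a"] * n)
        assert dc.edge_autocorrelation(net, meta, "a") == pytest.approx(rho, abs=0.05)

    def test_small_network_rejected(self, rng):
        net = dc.MultilayerNetwork(np.zeros((3, 3, 2)), node_ids=self.ids(3))
        meta = make_meta(["a", "b", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            dc.edge_autocorrelation(net, meta, "a")


class TestDetectEvents:
    def test_constant_partition_yields_nothing(self):
        assert dc.detect_events(part(np.zeros((20, 10))), min_size=2) == []

    def test_planted_split_and_merge(self):
        labels = np.zeros((45, 30), dtype=int)
        labels[30:, :] = 1
        labels[:15, 21:24] = 2  # 15 of community 0's 30 nodes leave on days 22-24
        events = dc.detect_events(part(labels), min_size=10)
        kinds = [(e.kind, e.day, e.size, e.duration) for e in events]
        assert ("split", 22, 15, 3) in kinds
        assert ("merge", 25, 15, 1) in kinds
        assert len(events) == 2
        split = [e for e in events if e.kind == "split"][0]
        assert split.node_set == tuple(range(15))
        assert split.source_community == 0

    def test_ground_truth_scenario_events(self, default_scenario):
        cfg, _, truth, _ = default_scenario
        events = dc.detect_events(truth, min_size=8)
        split_days = [e.day for e in events if e.kind == "split"]
        assert cfg.resolved_split_days()[0] in split_days
        assert cfg.resolved_secondary_days()[0] in split_days
        main = [e for e in events if e.kind == "split" and e.day == cfg.resolved_split_days()[0]][0]
        assert main.size == len(cfg.split_nodes())
        assert main.duration == cfg.resolved_split_days()[1] - cfg.resolved_split_days()[0] + 1

    def test_min_size_threshold_dominates(self):
        labels = np.zeros((12, 6), dtype=int)
        labels[:3, 3] = 1
        assert dc.detect_events(part(labels), min_size=5) == []

    def test_label_recycling_is_not_an_event(self):
        # community 1 exists before day l, so adopting it is not a split
        labels = np.zeros((12, 6), dtype=int)
        labels[10:, :] = 1
        labels[:5, 3] = 1
        assert dc.detect_events(part(labels), min_size=4) == []


class TestEdgeChangeAttribution:
    def test_degenerate_identical_layers(self, rng):
        M = rng.uniform(0.2, 0.8, (8, 8))
        M = 0.5 * (M + M.T)
        np.fill_diagonal(M, 0)
        net = dc.MultilayerNetwork(np.repeat(M[:, :, None], 3, axis=2),
                                   node_ids=[f"n{i}" for i in range(8)])
        meta = make_meta(["a"] * 8)
        res = dc.edge_change_attribution(net, meta, day=2, fraction=0.05)
        assert res["degenerate"]
        assert res["n_selected"] == int(np.ceil(0.05 * 28))

    def test_selection_count_rounds_up(self, rng):
        # 5 nodes -> 10 edges; fraction 0.2 -> exactly 2 edges
        A = rng.uniform(0.1, 0.9, (5, 5, 2))
        A = 0.5 * (A + A.transpose(1, 0, 2))
        for l in range(2):
            np.fill_diagonal(A[:, :, l], 0)
        net = dc.MultilayerNetwork(A, node_ids=[f"n{i}" for i in range(5)])
        meta = make_meta(["a"] * 5)
        res = dc.edge_change_attribution(net, meta, day=2, fraction=0.2)
        assert res["n_selected"] == 2

    def test_planted_boost_dominates_top_changes(self, default_scenario):
        """Largest day-21->22 increases concentrate in the split block."""
        cfg, net, _, meta = default_scenario
        res = dc.edge_change_attribution(net, meta, day=cfg.resolved_split_days()[0],
                                         fraction=0.05)
        top_net_pair = res["network_pairs"].index[0]
        assert top_net_pair == ("default_mode", "default_mode")
        top_sub_pair = res["subnetwork_pairs"].index[0]
        assert top_sub_pair == ("default_mode_B", "default_mode_B")

    def test_invalid_day_and_fraction(self, default_scenario):
        _, net, _, meta = default_scenario
        with pytest.raises(ValueError):
            dc.edge_change_attribution(net, meta, day=1)
        with pytest.raises(ValueError):
            dc.edge_change_attribution(net, meta, day=2, fraction=1.5)
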