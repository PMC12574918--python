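"""Movement networks, node metrics, motility densities and null models."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from tigermove import (
    active_stations,
    build_network,
    build_networks,
    compare_to_null,
    count_movers,
    motility,
    node_metrics,
    random_network_null,
)
from tigermove.network import to_graph
from tigermove.simulate import true_movement_counts

from helpers import brute_force_betweenness, make_detections


def det_frame(stations, start="2018-03-01", step_h=2):
    rows = [
        (pd.Timestamp(start) + pd.Timedelta(hours=step_h * i), "T1", s)
        for i, s in enumerate(stations)
    ]
    det = make_detections(rows)
    det["qc_status"] = "retained"
    return det


class TestActiveStations:
    def receivers(self):
        return pd.DataFrame(
            {
                "station_id": ["A", "B", "C"],
                "array": ["X", "X", "X"],
                "latitude": [25.0, 25.1, 25.2],
                "longitude": [-77.0, -77.1, -77.2],
                "depth_m": [10, 10, 10],
                "habitat": ["sand", "sand", "sand"],
                "install_date": pd.to_datetime(
                    ["2018-01-01", "2018-01-01", "2018-06-01"]
                ),
                "removal_date": pd.to_datetime(["2018-02-01", "2019-01-01", pd.NaT]),
            }
        )

    def test_removed_before_window_excluded(self):
        act = active_stations("2018-03-01", "2018-04-01", self.receivers())
        assert act == {"X": frozenset({"B"})}

    def test_full_study_receiver_always_included(self):
        act = active_stations("2018-07-01", "2018-08-01", self.receivers())
        assert "B" in act["X"] and "C" in act["X"]

    def test_one_day_overlap_included(self):
        # removal on the shark's first-detection day still overlaps by a day
        act = active_stations("2018-02-01", "2018-03-01", self.receivers())
        assert "A" in act["X"]


class TestBuildNetwork:
    def test_hand_enumerated_edges(self):
        det = det_frame(["S1", "S1", "S2", "S1", "S3"])
        net = build_network(det, "T1", frozenset({"S1", "S2", "S3"}))
        assert dict(net.edges) == {("S1", "S2"): 1, ("S2", "S1"): 1, ("S1", "S3"): 1}
        assert net.n_movements == 3

    def test_single_station_no_edges(self):
        det = det_frame(["S1", "S1", "S1"])
        net = build_network(det, "T1", frozenset({"S1", "S2"}))
        assert net.n_movements == 0 and not net.edges

    def test_inter_array_transitions_not_edges(self):
        det = det_frame(["N1", "N2", "E1", "E2"])
        arrays = pd.Series(
            {"N1": "NP", "N2": "NP", "E1": "GE", "E2": "GE"}
        )
        nets = build_networks(
            det,
            "T1",
            {"NP": frozenset({"N1", "N2"}), "GE": frozenset({"E1", "E2"})},
            arrays,
        )
        assert dict(nets["NP"].edges) == {("N1", "N2"): 1}
        assert dict(nets["GE"].edges) == {("E1", "E2"): 1}
        assert nets["NP"].inter_array_movements == 1

    def test_off_active_visit_flagged(self):
        det = det_frame(["S1", "S9"])
        with pytest.warns(UserWarning, match="S9"):
            net = build_network(det, "T1", frozenset({"S1", "S2"}))
        assert "S9" in net.off_active_visits
        assert "S9" in net.visited


class TestNodeMetrics:
    def test_directed_path_betweenness(self):
        net = build_network(
            det_frame(["A", "B", "C"]), "T1", frozenset({"A", "B", "C"})
        )
        nm = node_metrics(net).set_index("station_id")
        assert nm.loc["B", "betweenness"] == 1.0
        assert nm.loc["A", "betweenness"] == 0.0

    def test_complete_graph_zero_betweenness(self):
        seq = [a for pair in itertools.permutations("ABC", 2) for a in pair]
        net = build_network(det_frame(seq), "T1", frozenset("ABC"))
        g = to_graph(net)
        assert g.number_of_edges() == 6
        nm = node_metrics(net)
        assert (nm["betweenness"] == 0).all()

    def test_star_center_counts_ordered_leaf_pairs(self):
        # visits alternate center-leaf so all 8 center<->leaf edges exist
        seq = ["C", "L1", "C", "L2", "C", "L3", "C", "L4", "C"]
        net = build_network(det_frame(seq), "T1", frozenset(seq))
        nm = node_metrics(net).set_index("station_id")
        assert nm.loc["C", "betweenness"] == 12.0  # 4*3 ordered leaf pairs
        assert nm.loc["C", "connectivity"] == 4

    @pytest.mark.parametrize("seed", range(50))
    def test_betweenness_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        m = int(rng.integers(0, n * (n - 1) + 1))
        g = nx.gnm_random_graph(n, m, seed=seed, directed=True)
        got = nx.betweenness_centrality(g, normalized=False)
        want = brute_force_betweenness(g)
        for v in g.nodes:
            assert got[v] == pytest.approx(want[v], abs=1e-9)


class TestMotility:
    def test_all_ordered_pairs_gives_one(self):
        seq = [s for pair in itertools.permutations("ABCD", 2) for s in pair]
        net = build_network(det_frame(seq), "T1", frozenset("ABCD"))
        rec = motility(net)
        assert rec["edge_density"] == pytest.approx(1.0)

    def test_no_movements_zero_edge_density(self):
        net = build_network(det_frame(["A"]), "T1", frozenset("ABCD"))
        assert motility(net)["edge_density"] == 0.0

    def test_three_pairs_of_twenty(self):
        det = det_frame(["S1", "S2", "S1", "S3"])
        net = build_network(det, "T1", frozenset({"S1", "S2", "S3", "S4", "S5"}))
        rec = motility(net)
        assert rec["edge_density"] == pytest.approx(3 / 20)
        assert rec["node_density"] == pytest.approx(3 / 5)

    def test_undirected_convention_denominator(self):
        det = det_frame(["S1", "S2", "S1"])
        net = build_network(det, "T1", frozenset({"S1", "S2", "S3", "S4"}))
        rec = motility(net, directed=False)
        assert rec["edge_density"] == pytest.approx(1 / 6)

    def test_single_active_station_flagged(self):
        net = build_network(det_frame(["A"]), "T1", frozenset("A"))
        rec = motility(net)
        assert rec["edge_density"] == 0.0 and not rec["edge_density_defined"]

    @pytest.mark.parametrize("seed", range(5))
    def test_node_density_monotone_and_truncation_shrinks_edges(self, seed):
        # any subset shrinks the visited set; a prefix of the track can
        # only traverse a subset of the consecutive station pairs
        rng = np.random.default_rng(seed)
        stations = [f"S{rng.integers(1, 7)}" for _ in range(80)]
        det = det_frame(stations)
        active = frozenset(f"S{i}" for i in range(1, 7))
        full = motility(build_network(det, "T1", active))
        keep = rng.random(len(det)) < 0.5
        sub = motility(build_network(det[keep], "T1", active))
        assert sub["node_density"] <= full["node_density"] + 1e-12
        prefix = motility(build_network(det.iloc[:40], "T1", active))
        assert prefix["edge_density"] <= full["edge_density"] + 1e-12

    def test_densities_match_pair_enumeration_oracle(self, bundle):
        # independent recount of visited stations and ordered pairs from
        # the retained detection stream
        nets = bundle["networks"]
        motil = bundle["motility"].set_index(["shark_id", "array"])
        for (sid, arr), net in list(nets.items())[:20]:
            rec = motil.loc[(sid, arr)]
            pairs = set(net.edges)
            n = len(net.nodes)
            assert rec["edge_density"] == pytest.approx(
                len(pairs) / (n * (n - 1)) if n > 1 else 0.0
            )
            assert rec["node_density"] == pytest.approx(len(net.visited) / n)


class TestGroupNetworks:
    def test_group_edges_are_member_sum(self):
        from tigermove.network import group_network

        nets = [
            build_network(det_frame(["A", "B", "A"]), "T1", frozenset("AB")),
            build_network(det_frame(["B", "C", "B"]), "T2", frozenset("BC")),
        ]
        grp = group_network(nets, "juvenile")
        assert dict(grp.edges) == {
            ("A", "B"): 1, ("B", "A"): 1, ("B", "C"): 1, ("C", "B"): 1
        }
        assert grp.nodes == frozenset("ABC")  # union of member active sets
        assert grp.n_movements == 4

    def test_mixed_arrays_rejected(self):
        from tigermove.network import group_network

        a = build_network(det_frame(["A", "B"]), "T1", frozenset("AB"), array="NP")
        b = build_network(det_frame(["C", "D"]), "T2", frozenset("CD"), array="GE")
        with pytest.raises(ValueError):
            group_network([a, b], "g")


class TestNullModel:
    def test_invalid_edge_count_rejected(self):
        with pytest.raises(ValueError):
            random_network_null(4, 99, reps=100)

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            random_network_null(4, 4, reps=10)

    def test_degenerate_comparison_flagged(self):
        null = np.zeros((100, 4))
        res = compare_to_null([0.0, 0.0, 0.0, 0.0], null)
        assert res.p_value == 1.0 and res.degenerate

    def test_corridor_graph_differs_from_random(self):
        # a linear corridor of 16 stations: interior nodes carry far more
        # shortest paths than G(n, m) nodes with the same edge budget
        stations = [f"S{i:02d}" for i in range(16)]
        seq = []
        for s in stations:
            seq.append(s)
        for s in reversed(stations[:-1]):
            seq.append(s)
        net = build_network(det_frame(seq), "T1", frozenset(stations))
        nm = node_metrics(net)
        null = random_network_null(16, len(net.edges), reps=300, seed=0)
        res = compare_to_null(nm["betweenness"].to_numpy(), null)
        assert res.p_value < 0.01


@pytest.fixture(scope="module")
def perfect():
    import tigermove as tm
    from conftest import small_config

    cfg = small_config(
        seed=13,
        detection_prob=1.0,
        false_detection_rate=0.0,
        staggered_deployments=False,
    )
    receivers = tm.simulate_array(cfg)
    tags, truths = tm.simulate_cohort_and_tracks(cfg, receivers)
    det = tm.emit_detections(truths, receivers, cfg, tags)
    return cfg, receivers, tags, truths, det


class TestTruthRecovery:
    def test_visited_sets_recovered_exactly(self, perfect):
        cfg, receivers, tags, truths, det = perfect
        tag_of = tags.set_index("shark_id")["tag_id"].to_dict()
        for truth in truths:
            seen = set(
                det[det["tag_id"] == tag_of[truth.shark_id]]["station_id"]
            )
            assert seen == set(truth.visits["station_id"])

    def test_movement_counts_match_truth(self, perfect):
        cfg, receivers, tags, truths, det = perfect
        arrays = receivers.drop_duplicates("station_id").set_index("station_id")[
            "array"
        ]
        tag_of = tags.set_index("shark_id")["tag_id"].to_dict()
        for truth in truths:
            d = det[det["tag_id"] == tag_of[truth.shark_id]].assign(
                qc_status="retained"
            )
            act = {
                a: frozenset(g["station_id"])
                for a, g in receivers.groupby("array")
            }
            nets = build_networks(d, truth.shark_id, act, arrays)
            want = true_movement_counts(truth)
            for arr, net in nets.items():
                assert net.n_movements == want.get(arr, 0)


class TestExport:
    def test_graphml_round_trip(self, tmp_path):
        from tigermove.network import write_graphml

        net = build_network(
            det_frame(["A", "B", "A", "C"]), "T1", frozenset("ABC")
        )
        path = tmp_path / "net.graphml"
        write_graphml(net, path)
        g = nx.read_graphml(path)
        assert set(g.nodes) == {"A", "B", "C"}
        assert g["A"]["B"]["weight"] == 1


class TestCountMovers:
    def test_union_not_double_counted(self):
        recs = pd.DataFrame(
            {
                "shark_id": ["a", "a", "b", "c"],
                "array": ["NP", "GE", "NP", "GE"],
                "n_movements": [3, 2, 1, 0],
            }
        )
        got = count_movers(recs)
        assert got["total"] == 2
        assert got["per_array"] == {"NP": 2, "GE": 1}
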