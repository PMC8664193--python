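import logging
import math

import numpy as np
import pytest

from conftest import random_network
from ehc_access.accessibility import (
    DENSELY_POPULATED,
    RURAL,
    URBAN,
    TimeConstants,
    assign_quintiles,
    closest_facility,
    compute_access_table,
    compute_rt,
    compute_tpt,
    compute_tt,
    facility_travel_times,
    golden_hour_flag,
)
from ehc_access.road_network import (
    AMBULANCE_STATION,
    EMERGENCY_DEPARTMENT,
    Facility,
    RoadNetwork,
)

CONST = TimeConstants()


def station(fid, node):
    return Facility(fid, AMBULANCE_STATION, (0.0, 0.0), snapped_node=node)


def floyd_warshall_minutes(net: RoadNetwork) -> dict:
    """Brute-force all-pairs shortest travel times by triple iteration."""
    nodes = sorted(net.graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), math.inf)
    np.fill_diagonal(d, 0.0)
    for a, b, data in net.graph.edges(data=True):
        t = data["travel_min"]
        i, j = idx[a], idx[b]
        d[i, j] = min(d[i, j], t)
        d[j, i] = min(d[j, i], t)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return {(a, b): d[idx[a], idx[b]] for a in nodes for b in nodes}


class TestClosestFacility:
    def test_facility_at_target_gives_zero(self, path_graph):
        res = closest_facility(path_graph, [station("S1", 2)], 2)
        assert res.facility_id == "S1"
        assert res.travel_min == 0.0

    def test_single_path_sums_edge_times(self, path_graph):
        res = closest_facility(path_graph, [station("S1", 0)], 2)
        assert res.travel_min == pytest.approx(5.0)

    def test_tie_breaks_to_lowest_facility_id(self, path_graph):
        # stations at both ends are equidistant from nowhere; at node 1 the
        # left station is closer, so force an exact tie via equal edges
        net = RoadNetwork()
        for i, x in enumerate([0.0, 1000.0, 2000.0]):
            net.add_node(i, x, 0.0)
        net.add_edge(0, 1, 1000.0, 60.0)
        net.add_edge(1, 2, 1000.0, 60.0)
        res = closest_facility(net, [station("S2", 2), station("S1", 0)], 1)
        assert res.facility_id == "S1"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_floyd_warshall_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, 30)
        fac_nodes = rng.choice(30, size=3, replace=False)
        facs = [station(f"S{i}", int(n)) for i, n in enumerate(fac_nodes)]
        table = facility_travel_times(net, facs)
        ap = floyd_warshall_minutes(net)
        for target in net.graph.nodes:
            expected = min(ap[int(f.snapped_node), target] for f in facs)
            assert table[target].travel_min == pytest.approx(expected, abs=1e-9)

    def test_empty_facility_set_raises(self, path_graph):
        with pytest.raises(ValueError):
            closest_facility(path_graph, [], 0)


class TestComposition:
    def test_rt_adds_rural_activation(self):
        assert compute_rt(10.0, RURAL, CONST) == pytest.approx(12.9)

    def test_rt_adds_urban_activation_to_zero_travel(self):
        assert compute_rt(0.0, URBAN, CONST) == pytest.approx(1.4)

    def test_dense_and_urban_share_activation_constant(self):
        assert compute_rt(7.3, DENSELY_POPULATED, CONST) == compute_rt(7.3, URBAN, CONST)

    def test_tt_is_bare_travel_time(self):
        assert compute_tt(20.0) == 20.0
        assert compute_tt(0.0) == 0.0

    def test_tpt_rural_example(self):
        assert compute_tpt(12.9, 20.0, RURAL, CONST) == pytest.approx(48.0)

    def test_tpt_urban_example(self):
        assert compute_tpt(1.4, 0.0, URBAN, CONST) == pytest.approx(14.9)

    @pytest.mark.parametrize("atype", [URBAN, DENSELY_POPULATED, RURAL])
    def test_tpt_identity(self, atype):
        rt, tt = 9.7, 13.1
        tpt = compute_tpt(rt, tt, atype, CONST)
        assert tpt - rt - tt == pytest.approx(CONST.onscene(atype), abs=1e-12)

    def test_negative_inputs_raise(self):
        with pytest.raises(ValueError):
            compute_rt(-1.0, URBAN, CONST)
        with pytest.raises(ValueError):
            compute_tpt(-0.1, 0.0, URBAN, CONST)

    def test_unknown_area_type_raises(self):
        with pytest.raises(ValueError):
            compute_rt(1.0, "suburban", CONST)


class TestGoldenHour:
    @pytest.mark.parametrize("tpt, expected", [(48.0, True), (60.0, False), (108.8, False), (59.999, True)])
    def test_strict_threshold(self, tpt, expected):
        assert golden_hour_flag(tpt, CONST) is expected


class TestQuintiles:
    def test_even_split_of_ordered_values(self):
        labels = assign_quintiles(list(range(1, 11)))
        assert labels.tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_all_equal_values_split_by_stable_order(self):
        labels = assign_quintiles([4.0] * 10)
        assert labels.tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_fifth_quintile_holds_longest_times(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, size=53)
        labels = assign_quintiles(x)
        assert x[labels == 5].min() >= x[labels < 5].max()

    def test_group_sizes_differ_by_at_most_one(self):
        labels = assign_quintiles(np.arange(2520, dtype=float))
        counts = np.bincount(labels)[1:]
        assert counts.tolist() == [504] * 5

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError):
            assign_quintiles([1.0, 2.0, 3.0, 4.0])


def _tiny_region_tables(net):
    centroid_nodes = {f"A{i}": i for i in range(3)}
    area_types = {"A0": URBAN, "A1": DENSELY_POPULATED, "A2": RURAL}
    return centroid_nodes, area_types


def test_access_table_composition_and_flags(path_graph):
    centroid_nodes, area_types = _tiny_region_tables(path_graph)
    stations = [station("S1", 0)]
    hospitals = [Facility("H1", EMERGENCY_DEPARTMENT, (0, 0), snapped_node=2)]
    df = compute_access_table(path_graph, centroid_nodes, area_types, stations, hospitals)
    a0 = df[df.area_id == "A0"].iloc[0]
    assert a0.rt_min == pytest.approx(1.4)       # at the station
    assert a0.tt_min == pytest.approx(5.0)       # across the path
    assert a0.tpt_min == pytest.approx(1.4 + 5.0 + 13.5)
    assert bool(a0.within_golden_hour)
    a2 = df[df.area_id == "A2"].iloc[0]
    assert a2.tpt_min - a2.rt_min - a2.tt_min == pytest.approx(15.1, abs=1e-9)


def test_unreachable_area_excluded_with_warning(path_graph, caplog):
    path_graph.add_node(99, 9e6, 9e6)  # isolated junction
    centroid_nodes = {"A0": 0, "A1": 1, "A2": 2, "A9": 99}
    area_types = dict.fromkeys(centroid_nodes, URBAN)
    stations = [station("S1", 0)]
    hospitals = [Facility("H1", EMERGENCY_DEPARTMENT, (0, 0), snapped_node=0)]
    with caplog.at_level(logging.WARNING):
        df = compute_access_table(path_graph, centroid_nodes, area_types, stations, hospitals)
    assert "A9" in caplog.text
    assert set(df.area_id) == {"A0", "A1", "A2"}


class TestMonotonicity:
    """Adding a facility can only shorten (or preserve) routed times."""

    @pytest.mark.parametrize("seed", range(3))
    def test_extra_facility_never_increases_times(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_network(rng, 40)
        base = [station("S1", int(rng.integers(40))), station("S2", int(rng.integers(40)))]
        extra = base + [station("S3", int(rng.integers(40)))]
        before = facility_travel_times(net, base)
        after = facility_travel_times(net, extra)
        for node in net.graph.nodes:
            assert after[node].travel_min <= before[node].travel_min + 1e-12
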