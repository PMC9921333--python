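import numpy as np
import pandas as pd
import pytest

from velopath.population import (
    ClassThresholds,
    PopulationError,
    Station,
    TripTable,
    aggregate_by_station,
    availability_and_change,
    detour_distribution,
    ordered_od_pair_count,
    route_summary,
    voronoi_catchments,
)
from velopath.routing import OptimalRouteResult, Route, least_cost_path
from conftest import make_network


def trip_table(rows):
    return TripTable(
        pd.DataFrame(rows, columns=["origin_station", "destination_station", "trip_count"])
    )


class TestOrderedPairCount:
    @pytest.mark.parametrize("k", range(2, 31))
    def test_k_times_k_minus_one(self, k):
        assert ordered_od_pair_count(k) == k * (k - 1)

    def test_bike_share_system_scale(self):
        assert ordered_od_pair_count(242) == 58_322


class TestRouteSummary:
    def chain_net(self, n_edges, edge_len, **attrs):
        nodes = {f"n{i}": (edge_len * i, 0.0) for i in range(n_edges + 1)}
        edges = [(f"e{i}", f"n{i}", f"n{i+1}", dict(attrs)) for i in range(n_edges)]
        return make_network(nodes, edges)

    def test_total_minutes_at_speed(self):
        # 2500 m at 15 km/h -> 10 minutes
        net = self.chain_net(5, 500.0, aqi=1.5, noise_db=60.0, gvi=0.3)
        route = least_cost_path(net, "n0", "n5")
        rec = route_summary(net, route, speed_kmh=15.0)
        assert rec["total_minutes"] == pytest.approx(10.0)

    def test_below_threshold_everywhere_zero_class_minutes(self):
        net = self.chain_net(5, 500.0, aqi=1.5, noise_db=60.0, gvi=0.3)
        route = least_cost_path(net, "n0", "n5")
        rec = route_summary(net, route, speed_kmh=15.0)
        assert rec["minutes_noise_gt_db"] == 0.0

    def test_half_route_above_noise_threshold(self):
        # half of 2500 m at 70 dB -> 5 of 10 minutes in "noise > 65 dB"
        nodes = {f"n{i}": (250.0 * i, 0.0) for i in range(11)}
        edges = [
            (
                f"e{i}", f"n{i}", f"n{i+1}",
                dict(aqi=1.5, gvi=0.3, noise_db=70.0 if i < 5 else 60.0),
            )
            for i in range(10)
        ]
        net = make_network(nodes, edges)
        route = least_cost_path(net, "n0", "n10")
        rec = route_summary(net, route, speed_kmh=15.0)
        assert rec["minutes_noise_gt_db"] == pytest.approx(5.0)

    def test_class_minutes_monotone_in_threshold(self):
        net = self.chain_net(4, 300.0, aqi=2.5, noise_db=66.0, gvi=0.25)
        route = least_cost_path(net, "n0", "n4")
        minutes = [
            route_summary(net, route, 15.0, ClassThresholds(noise_gt_db=t))[
                "minutes_noise_gt_db"
            ]
            for t in (55.0, 65.0, 67.0, 75.0)
        ]
        assert all(a >= b for a, b in zip(minutes, minutes[1:]))

    def test_missing_exposure_rejected(self):
        net = self.chain_net(2, 100.0, aqi=2.0, noise_db=60.0)  # gvi missing
        route = least_cost_path(net, "n0", "n2")
        with pytest.raises(PopulationError, match="impute"):
            route_summary(net, route)


class TestVoronoiCatchments:
    def test_single_station_gets_whole_boundary(self):
        cells = voronoi_catchments([Station("s1", 50, 50)], (0, 0, 100, 100))
        assert cells["s1"].area == pytest.approx(100 * 100)

    def test_two_stations_split_by_perpendicular_bisector(self):
        cells = voronoi_catchments(
            [Station("s1", 25, 50), Station("s2", 75, 50)], (0, 0, 100, 100)
        )
        assert cells["s1"].area == pytest.approx(5000.0, rel=1e-9)
        assert cells["s2"].area == pytest.approx(5000.0, rel=1e-9)

    def test_four_corner_stations_equal_quadrants(self):
        stations = [
            Station("s1", 25, 25), Station("s2", 75, 25),
            Station("s3", 25, 75), Station("s4", 75, 75),
        ]
        cells = voronoi_catchments(stations, (0, 0, 100, 100))
        for sid in ("s1", "s2", "s3", "s4"):
            assert cells[sid].area == pytest.approx(2500.0, rel=1e-9)

    def test_cell_areas_sum_to_boundary_area(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(10, 990, size=(15, 2))
        stations = [Station(f"s{i}", x, y) for i, (x, y) in enumerate(pts)]
        cells = voronoi_catchments(stations, (0, 0, 1000, 1000))
        assert sum(c.area for c in cells.values()) == pytest.approx(1e6, rel=1e-6)

    def test_interior_points_nearest_own_station(self):
        rng = np.random.default_rng(10)
        pts = rng.uniform(10, 990, size=(8, 2))
        stations = [Station(f"s{i}", x, y) for i, (x, y) in enumerate(pts)]
        cells = voronoi_catchments(stations, (0, 0, 1000, 1000))
        samples = rng.uniform(0, 1000, size=(300, 2))
        for x, y in samples:
            d = np.hypot(pts[:, 0] - x, pts[:, 1] - y)
            nearest = f"s{int(np.argmin(d))}"
            from shapely.geometry import Point

            owners = [sid for sid, cell in cells.items() if cell.covers(Point(x, y))]
            assert nearest in owners  # boundary points may belong to several

    def test_duplicate_station_coordinates_rejected(self):
        with pytest.raises(PopulationError, match="duplicate"):
            voronoi_catchments(
                [Station("s1", 10, 10), Station("s2", 10, 10)], (0, 0, 100, 100)
            )


def summaries_df(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "origin_station", "destination_station", "route_set",
            "mean_aqi", "mean_noise_db", "mean_gvi", "length_m",
        ],
    )


class TestAggregateByStation:
    def test_uniform_trip_counts_weighted_equals_unweighted(self):
        rng = np.random.default_rng(4)
        rows, trips_rows = [], []
        for d in range(1, 6):
            rows.append(("s0", f"s{d}", "shortest",
                         rng.uniform(1, 3), rng.uniform(50, 70), rng.uniform(0, 0.5),
                         rng.uniform(500, 3000)))
            trips_rows.append(("s0", f"s{d}", 7))
        trips = trip_table(trips_rows)
        unw = aggregate_by_station(summaries_df(rows), trips, weighted=False)
        w = aggregate_by_station(summaries_df(rows), trips, weighted=True)
        for col in ("mean_aqi", "mean_noise_db", "mean_gvi", "length_m"):
            assert unw[col].iloc[0] == pytest.approx(w[col].iloc[0])

    def test_single_od_pair_mean_is_route_value(self):
        rows = [("s0", "s1", "shortest", 2.2, 61.0, 0.3, 1500.0)]
        out = aggregate_by_station(
            summaries_df(rows), trip_table([("s0", "s1", 4)]), weighted=True
        )
        assert out["mean_noise_db"].iloc[0] == 61.0

    def test_hand_weighted_mean(self):
        # means {60, 70} dB with counts {3, 1} -> 62.5
        rows = [
            ("s0", "s1", "shortest", 2.0, 60.0, 0.2, 1000.0),
            ("s0", "s2", "shortest", 2.0, 70.0, 0.2, 1000.0),
        ]
        trips = trip_table([("s0", "s1", 3), ("s0", "s2", 1)])
        out = aggregate_by_station(summaries_df(rows), trips, weighted=True)
        assert out["mean_noise_db"].iloc[0] == pytest.approx(62.5)

    def test_trips_referencing_unrouted_pairs_rejected(self):
        rows = [("s0", "s1", "shortest", 2.0, 60.0, 0.2, 1000.0)]
        trips = trip_table([("s0", "s9", 3)])
        with pytest.raises(PopulationError, match="unrouted"):
            aggregate_by_station(summaries_df(rows), trips, weighted=True)


def _route(length, noise, edges=("x",)):
    return Route(
        edge_ids=tuple(edges), node_ids=("u", "v"), length=length,
        mean_aqi=2.0, mean_noise_db=noise, mean_gvi=0.2,
        composite_cost=length, sensitivity_used=0.0,
    )


def _result(shortest_noise, optimal_noise, extra_m=0.0):
    shortest = _route(1000.0, shortest_noise)
    if optimal_noise is None:
        return {
            e: OptimalRouteResult(shortest, shortest, False, 0.0, e)
            for e in ("aqi", "noise", "gvi")
        }
    optimal = _route(1000.0 + extra_m, optimal_noise, edges=("y",))
    out = {}
    for e in ("aqi", "noise", "gvi"):
        if e == "noise":
            out[e] = OptimalRouteResult(
                shortest, optimal, True, optimal_noise - shortest_noise, e
            )
        else:
            out[e] = OptimalRouteResult(shortest, shortest, False, 0.0, e)
    return out


class TestAvailabilityAndChange:
    def test_no_pair_improves(self):
        results = {("s0", "s1"): _result(60.0, None)}
        trips = trip_table([("s0", "s1", 2)])
        table = availability_and_change(results, trips)
        row = table[(table.route_set == "noise") & ~table.trip_weighted].iloc[0]
        assert row.share_improved_pct == 0.0
        assert np.isnan(row.mean_exposure_change)

    def test_every_pair_improves_by_one_db(self):
        results = {
            ("s0", "s1"): _result(60.0, 59.0),
            ("s1", "s0"): _result(62.0, 61.0),
        }
        trips = trip_table([("s0", "s1", 2), ("s1", "s0", 5)])
        table = availability_and_change(results, trips)
        for weighted in (False, True):
            row = table[
                (table.route_set == "noise") & (table.trip_weighted == weighted)
            ].iloc[0]
            assert row.share_improved_pct == pytest.approx(100.0)
            assert row.mean_exposure_change == pytest.approx(-1.0)

    def test_conditional_mean_change(self):
        # 3 pairs, 2 improving with changes {-4, -6} -> share 66.7%, mean -5
        results = {
            ("s0", "s1"): _result(60.0, 56.0),
            ("s0", "s2"): _result(60.0, 54.0),
            ("s0", "s3"): _result(60.0, None),
        }
        trips = trip_table([("s0", "s1", 1), ("s0", "s2", 1), ("s0", "s3", 1)])
        table = availability_and_change(results, trips)
        row = table[(table.route_set == "noise") & ~table.trip_weighted].iloc[0]
        assert row.share_improved_pct == pytest.approx(200.0 / 3.0)
        assert row.mean_exposure_change == pytest.approx(-5.0)

    def test_additional_distance_conditional_on_improvement(self):
        results = {
            ("s0", "s1"): _result(60.0, 55.0, extra_m=120.0),
            ("s0", "s2"): _result(60.0, None),
        }
        trips = trip_table([("s0", "s1", 1), ("s0", "s2", 1)])
        table = availability_and_change(results, trips)
        row = table[(table.route_set == "noise") & ~table.trip_weighted].iloc[0]
        assert row.mean_additional_distance_m == pytest.approx(120.0)
        assert row.n_improved == 1


class TestDetourDistribution:
    def test_all_optimal_equal_shortest(self):
        det = {("s0", "s1"): {"aqi": 0.0, "noise": 0.0, "gvi": 0.0}}
        trips = trip_table([("s0", "s1", 3)])
        hist, shares = detour_distribution(det, trips)
        assert (shares["share_within_pct"] == 100.0).all()

    def test_single_pair_beyond_threshold(self):
        det = {("s0", "s1"): {"aqi": 0.2, "noise": 0.2, "gvi": 0.2}}
        trips = trip_table([("s0", "s1", 3)])
        _, shares = detour_distribution(det, trips, max_detour=0.15)
        assert (shares["share_within_pct"] == 0.0).all()

    def test_counting_share(self):
        # detours {5%, 10%, 20%}, threshold 15% -> 2/3 within
        det = {
            ("s0", "s1"): {"aqi": 0.05, "noise": 0.05, "gvi": 0.05},
            ("s0", "s2"): {"aqi": 0.10, "noise": 0.10, "gvi": 0.10},
            ("s0", "s3"): {"aqi": 0.20, "noise": 0.20, "gvi": 0.20},
        }
        trips = trip_table([("s0", "s1", 1), ("s0", "s2", 1), ("s0", "s3", 1)])
        hist, shares = detour_distribution(det, trips, max_detour=0.15)
        assert shares["share_within_pct"].iloc[0] == pytest.approx(200.0 / 3.0)
        noise_hist = hist[hist.exposure_type == "noise"]
        assert noise_hist["count"].sum() == 3


class TestTripTable:
    def test_self_loops_dropped(self):
        t = trip_table([("s0", "s0", 5), ("s0", "s1", 2)])
        assert len(t.df) == 1 and t.total_trips == 2

    def test_negative_counts_rejected(self):
        with pytest.raises(PopulationError):
            trip_table([("s0", "s1", -1)])

    def test_unknown_station_rejected(self):
        with pytest.raises(PopulationError):
            TripTable(
                pd.DataFrame(
                    [("s0", "s9", 1)],
                    columns=["origin_station", "destination_station", "trip_count"],
                ),
                stations=[Station("s0", 0, 0), Station("s1", 1, 1)],
            )
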