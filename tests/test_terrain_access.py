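"""Slope extraction, resistance classification, edge costs, accessibility."""

import math

import networkx as nx
import numpy as np
import pytest

from eldermatch.gridio import AsciiGrid
from eldermatch.terrain_access import (
    DEFAULT_ELEVATION_CLASSES,
    DEFAULT_SLOPE_CLASSES,
    accessibility,
    classify_resistance,
    comprehensive_resistance,
    edge_cost,
    isochrone,
    slope_from_dem,
)


def horn_slope_direct(z: np.ndarray, cellsize: float, r: int, c: int) -> float:
    """Independent single-cell Horn evaluation with edge replication."""
    nr, nc = z.shape
    get = lambda i, j: z[min(max(i, 0), nr - 1), min(max(j, 0), nc - 1)]
    a, b, cc = get(r - 1, c - 1), get(r - 1, c), get(r - 1, c + 1)
    d, f = get(r, c - 1), get(r, c + 1)
    g, h, i = get(r + 1, c - 1), get(r + 1, c), get(r + 1, c + 1)
    dzdx = ((cc + 2 * f + i) - (a + 2 * d + g)) / (8 * cellsize)
    dzdy = ((a + 2 * b + cc) - (g + 2 * h + i)) / (8 * cellsize)
    return math.degrees(math.atan(math.hypot(dzdx, dzdy)))


class TestSlope:
    def test_flat_raster_all_zero(self):
        dem = AsciiGrid(np.full((6, 6), 500.0), 0, 0, 30.0)
        assert np.allclose(slope_from_dem(dem).data, 0.0)

    def test_unit_gradient_plane_is_45_degrees_interior(self):
        z = np.tile(np.arange(8, dtype=float), (8, 1))  # +1 m per metre of x
        slope = slope_from_dem(AsciiGrid(z, 0, 0, 1.0)).data
        assert np.allclose(slope[1:-1, 1:-1], 45.0)

    def test_matches_direct_horn_evaluation(self, rng):
        z = rng.uniform(1000, 2000, size=(5, 5))
        dem = AsciiGrid(z, 0, 0, 25.0)
        slope = slope_from_dem(dem).data
        for r in range(5):
            for c in range(5):
                assert slope[r, c] == pytest.approx(horn_slope_direct(z, 25.0, r, c))

    def test_rejects_degenerate_raster(self):
        with pytest.raises(ValueError):
            slope_from_dem(AsciiGrid(np.ones((1, 9)), 0, 0, 30.0))


class TestClassification:
    @pytest.mark.parametrize(
        "value,classes,expected",
        [
            (10.0, DEFAULT_SLOPE_CLASSES, 1.2),      # gentle slope band
            (0.0, DEFAULT_SLOPE_CLASSES, 1.0),       # lowest class
            (5.0, DEFAULT_SLOPE_CLASSES, 1.0),       # boundary goes low
            (50.0, DEFAULT_SLOPE_CLASSES, 3.0),
            (3500.0, DEFAULT_ELEVATION_CLASSES, 1.5),  # boundary goes low
            (4000.0, DEFAULT_ELEVATION_CLASSES, 2.0),
        ],
    )
    def test_band_assignment(self, value, classes, expected):
        assert classify_resistance(value, classes) == expected

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            classify_resistance(-1.0, DEFAULT_SLOPE_CLASSES)

    @pytest.mark.parametrize(
        "coefs,expected",
        [((1.0, 1.0, 0.8), 0.94), ((1.2, 1.2, 1.2), 1.2), ((3.0, 2.0, 2.0), 2.4)],
    )
    def test_comprehensive_resistance_arithmetic(self, coefs, expected):
        assert comprehensive_resistance(*coefs) == pytest.approx(expected)

    def test_comprehensive_resistance_rejects_bad_weights(self):
        with pytest.raises(ValueError):
            comprehensive_resistance(1.0, 1.0, 1.0, weights=(0.5, 0.5, 0.5))
        # explicit override allowed
        assert comprehensive_resistance(1.0, 1.0, 1.0, weights=(0.5, 0.5, 0.5), allow_unnormalized=True) == 1.5

    def test_resistance_surface_bounds(self):
        """Min/max of the overlay given the default coefficient tables."""
        slopes = [c for _, c in DEFAULT_SLOPE_CLASSES]
        elevs = [c for _, c in DEFAULT_ELEVATION_CLASSES]
        roads = [0.8, 1.0, 1.2, 1.5, 2.0]
        vals = [
            comprehensive_resistance(s, e, r)
            for s in slopes
            for e in elevs
            for r in roads
        ]
        # min = 1.0*0.4 + 1.0*0.3 + 0.8*0.3; max = 3.0*0.4 + 2.0*0.3 + 2.0*0.3
        assert min(vals) == pytest.approx(0.94)
        assert max(vals) == pytest.approx(2.4)


@pytest.fixture()
def flat_dem():
    return AsciiGrid(np.full((10, 10), 100.0), 0.0, 0.0, 2000.0)


class TestEdgeCost:
    def test_flat_lowland_highway_hand_value(self, flat_dem):
        slope = slope_from_dem(flat_dem)
        cost = edge_cost((1000, 1000), (13000, 1000), 12_000, "highway", flat_dem, slope)
        assert cost == pytest.approx(12 / 120 * 0.94)

    def test_cost_linear_in_length(self, flat_dem):
        slope = slope_from_dem(flat_dem)
        c1 = edge_cost((0, 0), (6000, 0), 6000, "county", flat_dem, slope)
        c2 = edge_cost((0, 0), (12000, 0), 12000, "county", flat_dem, slope)
        assert c2 == pytest.approx(2 * c1)

    def test_rural_vs_highway_cost_ratio(self, flat_dem):
        slope = slope_from_dem(flat_dem)
        hw = edge_cost((0, 0), (10000, 0), 10000, "highway", flat_dem, slope)
        ru = edge_cost((0, 0), (10000, 0), 10000, "rural", flat_dem, slope)
        # speed ratio 120/20 times resistance ratio 1.30/0.94
        assert ru / hw == pytest.approx((120 / 20) * (1.30 / 0.94))

    def test_unknown_road_class_rejected(self, flat_dem):
        slope = slope_from_dem(flat_dem)
        with pytest.raises(KeyError):
            edge_cost((0, 0), (1, 0), 1.0, "footpath", flat_dem, slope)


def toy_graph():
    g = nx.Graph()
    coords = {"a": (0, 0), "b": (1, 0), "c": (2, 0)}
    for n, (x, y) in coords.items():
        g.add_node(n, x=x, y=y)
    g.add_edge("a", "b", cost=0.5)
    g.add_edge("b", "c", cost=0.25)
    g.add_edge("a", "c", cost=1.0)
    return g


class TestAccessibility:
    def units(self):
        return [
            {"unit_id": "a", "x": 0, "y": 0, "pop_65plus": 2000},
            {"unit_id": "c", "x": 2, "y": 0, "pop_65plus": 1000},
        ]

    def facilities(self):
        return [{"x": 1, "y": 0, "beds": 100}, {"x": 2, "y": 0, "beds": 50}]

    def test_infinite_budget_saturates(self):
        scores = accessibility(self.units(), self.facilities(), toy_graph(), "service_area", math.inf)
        by = {s.unit_id: s.S for s in scores}
        assert by["a"] == pytest.approx(150 / 2.0)
        assert by["c"] == pytest.approx(150 / 1.0)

    def test_zero_budget_counts_colocated_only(self):
        scores = accessibility(self.units(), self.facilities(), toy_graph(), "service_area", 0.0)
        by = {s.unit_id: s.S for s in scores}
        assert by["a"] == 0.0
        assert by["c"] == pytest.approx(50 / 1.0)

    def test_matches_exhaustive_path_enumeration(self):
        """Service-area S from Dijkstra equals brute-force least costs."""
        g = toy_graph()
        budget = 0.6

        def brute_cost(u, v):
            return min(
                sum(g[a][b]["cost"] for a, b in zip(path, path[1:]))
                for path in nx.all_simple_paths(g, u, v)
            ) if u != v else 0.0

        scores = {s.unit_id: s.S for s in accessibility(self.units(), self.facilities(), g, "service_area", budget)}
        for unit in self.units():
            expected = sum(
                f["beds"]
                for f in self.facilities()
                if brute_cost(unit["unit_id"], "b" if f["x"] == 1 else "c") <= budget
            ) / (unit["pop_65plus"] / 1000)
            assert scores[unit["unit_id"]] == pytest.approx(expected)

    def test_monotone_in_budget_and_facilities(self):
        budgets = [0.0, 0.3, 0.6, 1.0, 2.0]
        prev = None
        for b in budgets:
            cur = {s.unit_id: s.S for s in accessibility(self.units(), self.facilities(), toy_graph(), "service_area", b)}
            if prev is not None:
                assert all(cur[u] >= prev[u] for u in cur)
            prev = cur
        more = self.facilities() + [{"x": 0, "y": 0, "beds": 10}]
        bigger = {s.unit_id: s.S for s in accessibility(self.units(), more, toy_graph(), "service_area", 1.0)}
        base = {s.unit_id: s.S for s in accessibility(self.units(), self.facilities(), toy_graph(), "service_area", 1.0)}
        assert all(bigger[u] >= base[u] for u in base)

    def test_zero_elderly_reported_missing(self):
        units = [{"unit_id": "a", "x": 0, "y": 0, "pop_65plus": 0}]
        (score,) = accessibility(units, self.facilities(), toy_graph(), "service_area", 1.0)
        assert math.isnan(score.S)

    def test_gravity_mode_discounts_by_cost(self):
        scores = {s.unit_id: s.S for s in accessibility(self.units(), self.facilities(), toy_graph(), "gravity", 1.0)}
        expected_a = (100 * math.exp(-0.5) + 50 * math.exp(-0.75)) / 2.0
        assert scores["a"] == pytest.approx(expected_a)


class TestIsochrone:
    def test_zero_threshold_gives_sources(self):
        assert isochrone(toy_graph(), ["a"], [0.0]) == [{"a"}]

    def test_nested_on_random_graphs(self, rng):
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.35, seed=int(rng.integers(1e6)))
            for u, v in g.edges:
                g.edges[u, v]["cost"] = float(rng.uniform(0.1, 2.0))
            sets = isochrone(g, [0], [0.2, 0.5, 1.0, 3.0, 100.0])
            for s1, s2 in zip(sets, sets[1:]):
                assert s1 <= s2
            assert sets[-1] == set(nx.node_connected_component(g, 0))

    def test_empty_thresholds_rejected(self):
        with pytest.raises(ValueError):
            isochrone(toy_graph(), ["a"], [])
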