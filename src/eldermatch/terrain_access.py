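"""Terrain-resistance surfaces and cost-weighted network accessibility.

Travel cost on a road segment is free-flow time (length / class speed)
multiplied by a comprehensive terrain-resistance coefficient, a weighted
overlay of slope, elevation, and road-class resistances
(weights 0.4 / 0.3 / 0.3).  Per-unit accessibility is then either

* ``service_area`` — beds reachable within a least-cost budget per
  1000 residents aged 65+, mirroring a GIS Service Area workflow, or
* ``gravity`` — exponentially cost-discounted beds per 1000 elderly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from eldermatch.gridio import AsciiGrid

logger = logging.getLogger(__name__)

#: (upper bound, coefficient) tables; intervals are right-closed, the first
#: class starts at 0.  Slope bounds in degrees, elevation bounds in metres.
DEFAULT_SLOPE_CLASSES: tuple[tuple[float, float], ...] = (
    (5.0, 1.0),
    (15.0, 1.2),
    (25.0, 1.5),
    (35.0, 2.0),
    (math.inf, 3.0),
)
DEFAULT_ELEVATION_CLASSES: tuple[tuple[float, float], ...] = (
    (1500.0, 1.0),
    (2500.0, 1.2),
    (3500.0, 1.5),
    (math.inf, 2.0),
)
#: road class -> (design speed km/h, resistance coefficient)
DEFAULT_ROAD_CLASSES: dict[str, tuple[float, float]] = {
    "highway": (120.0, 0.8),
    "national": (80.0, 1.0),
    "provincial": (60.0, 1.2),
    "county": (40.0, 1.5),
    "rural": (20.0, 2.0),
}
DEFAULT_WEIGHTS: tuple[float, float, float] = (0.4, 0.3, 0.3)


@dataclass
class ResistanceConfig:
    """Classification tables and overlay weights for the resistance surface."""

    slope_classes: tuple[tuple[float, float], ...] = DEFAULT_SLOPE_CLASSES
    elevation_classes: tuple[tuple[float, float], ...] = DEFAULT_ELEVATION_CLASSES
    road_classes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ROAD_CLASSES)
    )
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    samples_per_edge: int = 5

    def __post_init__(self) -> None:
        for classes in (self.slope_classes, self.elevation_classes):
            bounds = [b for b, _ in classes]
            if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
                raise ValueError("class bounds must be strictly increasing")
            if any(c <= 0 for _, c in classes):
                raise ValueError("resistance coefficients must be positive")
        if not math.isclose(sum(self.weights), 1.0, abs_tol=1e-9):
            raise ValueError("overlay weights must sum to 1")
        if self.samples_per_edge < 2:
            raise ValueError("need at least 2 sample points per edge")


@dataclass
class AccessibilityScore:
    unit_id: str
    S: float  # beds per 1000 elderly (possibly cost-discounted); NaN if undefined
    mode: str
    budget: float


def slope_from_dem(dem: AsciiGrid) -> AsciiGrid:
    """Per-cell slope in degrees by Horn's 3x3 finite-difference method.

    Border cells are handled by edge replication.  Output is in [0, 90).
    """
    z = dem.data
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("DEM must have at least 3x3 cells for slope extraction")
    p = np.pad(z, 1, mode="edge")
    # 3x3 neighbourhood, compass naming: a b c / d e f / g h i (north up).
    a = p[:-2, :-2]; b = p[:-2, 1:-1]; c = p[:-2, 2:]
    d = p[1:-1, :-2]; f = p[1:-1, 2:]
    g = p[2:, :-2]; h = p[2:, 1:-1]; i = p[2:, 2:]
    dz_dx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * dem.cellsize)
    dz_dy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * dem.cellsize)
    slope = np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))
    return AsciiGrid(slope, dem.xllcorner, dem.yllcorner, dem.cellsize, dem.nodata)


def classify_resistance(value: float, classes: tuple[tuple[float, float], ...]) -> float:
    """Resistance coefficient of the first class whose upper bound >= value.

    Intervals are right-closed: a value exactly on a boundary takes the lower
    class's coefficient.
    """
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"cannot classify value {value!r}")
    for upper, coef in classes:
        if value <= upper:
            return coef
    raise ValueError("class table has no covering upper bound")  # pragma: no cover


def comprehensive_resistance(
    slope_coef: float,
    elev_coef: float,
    road_coef: float,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    *,
    allow_unnormalized: bool = False,
) -> float:
    """Weighted overlay: slope*w1 + elevation*w2 + road*w3."""
    if min(slope_coef, elev_coef, road_coef) <= 0:
        raise ValueError("resistance coefficients must be positive")
    if not allow_unnormalized and not math.isclose(sum(weights), 1.0, abs_tol=1e-9):
        raise ValueError("weights must sum to 1 (or pass allow_unnormalized=True)")
    return slope_coef * weights[0] + elev_coef * weights[1] + road_coef * weights[2]


def edge_cost(
    p1: tuple[float, float],
    p2: tuple[float, float],
    length_m: float,
    road_class: str,
    dem: AsciiGrid,
    slope: AsciiGrid,
    config: ResistanceConfig | None = None,
) -> float:
    """Travel cost (hours-equivalent) of one road segment.

    Slope and elevation coefficients come from mean raster values sampled at
    evenly spaced points along the segment; the road coefficient and speed
    from the segment's class.  cost = (length / speed) * overlay resistance.
    """
    config = config or ResistanceConfig()
    if road_class not in config.road_classes:
        raise KeyError(f"unknown road class {road_class!r}")
    speed_kmh, road_coef = config.road_classes[road_class]
    ts = np.linspace(0.0, 1.0, config.samples_per_edge)
    xs = p1[0] + ts * (p2[0] - p1[0])
    ys = p1[1] + ts * (p2[1] - p1[1])
    mean_slope = float(np.mean([slope.value_at(x, y) for x, y in zip(xs, ys)]))
    mean_elev = float(np.mean([dem.value_at(x, y) for x, y in zip(xs, ys)]))
    resistance = comprehensive_resistance(
        classify_resistance(mean_slope, config.slope_classes),
        classify_resistance(mean_elev, config.elevation_classes),
        road_coef,
        config.weights,
    )
    return (length_m / 1000.0) / speed_kmh * resistance


def build_cost_graph(
    nodes: dict[str, tuple[float, float]],
    edges: list[tuple[str, str, float, str]],
    dem: AsciiGrid,
    config: ResistanceConfig | None = None,
) -> nx.Graph:
    """Undirected road graph with a ``cost`` attribute on every edge.

    ``edges`` rows are (from_node, to_node, length_m, road_class).
    """
    config = config or ResistanceConfig()
    slope = slope_from_dem(dem)
    g = nx.Graph()
    for node_id, (x, y) in nodes.items():
        g.add_node(node_id, x=x, y=y)
    for u, v, length_m, road_class in edges:
        cost = edge_cost(nodes[u], nodes[v], length_m, road_class, dem, slope, config)
        g.add_edge(u, v, cost=cost, length_m=length_m, road_class=road_class)
    return g


def snap_to_node(graph: nx.Graph, x: float, y: float) -> str:
    """Nearest graph node by Euclidean distance."""
    return min(
        graph.nodes,
        key=lambda n: (graph.nodes[n]["x"] - x) ** 2 + (graph.nodes[n]["y"] - y) ** 2,
    )


def accessibility(
    units: list[dict],
    facilities: list[dict],
    graph: nx.Graph,
    mode: str = "service_area",
    budget: float = 1.0,
) -> list[AccessibilityScore]:
    """Per-unit facility accessibility over the cost-weighted network.

    ``units`` rows need unit_id, centroid x/y and pop_65plus; ``facilities``
    rows need x/y and beds.  service_area: beds within the least-cost budget
    per 1000 elderly.  gravity: sum of beds * exp(-cost/budget) per 1000
    elderly.  Units with zero elderly population get S = NaN with a warning;
    unreachable facilities contribute zero.
    """
    if mode not in ("service_area", "gravity"):
        raise ValueError(f"unknown accessibility mode {mode!r}")
    if budget < 0:
        raise ValueError("budget must be non-negative")
    fac_nodes = [(snap_to_node(graph, f["x"], f["y"]), float(f["beds"])) for f in facilities]
    # one Dijkstra per distinct facility node, not per facility
    dist_from: dict[str, dict[str, float]] = {}
    for node, _ in fac_nodes:
        if node not in dist_from:
            dist_from[node] = nx.single_source_dijkstra_path_length(graph, node, weight="cost")
    scores = []
    for unit in units:
        unit_node = snap_to_node(graph, unit["x"], unit["y"])
        elderly = float(unit["pop_65plus"])
        if elderly <= 0:
            logger.warning("unit %s has no elderly population; S undefined", unit["unit_id"])
            scores.append(AccessibilityScore(unit["unit_id"], float("nan"), mode, budget))
            continue
        total = 0.0
        for node, beds in fac_nodes:
            cost = dist_from[node].get(unit_node)
            if cost is None:
                continue
            if mode == "service_area":
                if cost <= budget:
                    total += beds
            else:
                total += beds * math.exp(-cost / budget)
        scores.append(AccessibilityScore(unit["unit_id"], total / (elderly / 1000.0), mode, budget))
    return scores


def isochrone(
    graph: nx.Graph,
    sources: list[str],
    thresholds: list[float],
) -> list[set[str]]:
    """Nested reachable node sets at increasing cost thresholds."""
    if not thresholds:
        raise ValueError("threshold list must be non-empty")
    if any(t2 < t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be non-decreasing")
    dist = nx.multi_source_dijkstra_path_length(graph, set(sources), weight="cost")
    return [{n for n, d in dist.items() if d <= t} for t in thresholds]
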