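"""Road-network travel times between demand regions and facilities.

Travel impedance is drive time in minutes over a hierarchical road
network. Each segment carries one of four road classes with a free-flow
speed (defaults 80 km/h expressway, 60 main, 40 secondary, 30 local);
edge cost is length / speed. Origins (neighbourhood centroids, ideally
demand-weighted) and destinations (hospitals) attach to their nearest
network node; access/egress time from the point to that node is ignored.
The network is undirected, so the origin-destination matrix transposes
when the two point sets are swapped. Unreachable pairs carry ``inf``
rather than raising, so partial networks degrade gracefully.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import LineString

__all__ = [
    "ROAD_CLASSES",
    "RoadSegment",
    "SpeedModel",
    "TravelTimeMatrix",
    "weighted_centroid",
    "build_network",
    "travel_time_matrix",
    "closest_facility_distance",
]

#: Road hierarchy classes, fastest first.
ROAD_CLASSES = ("expressway", "main", "secondary", "local")

# Node coordinates are rounded to this many decimals (metres) so segment
# endpoints that should touch actually share a graph node.
_SNAP_DECIMALS = 6


@dataclass(frozen=True)
class RoadSegment:
    """A polyline road segment with a hierarchy class."""

    geometry: tuple[tuple[float, float], ...]
    road_class: str

    def __post_init__(self) -> None:
        if self.road_class not in ROAD_CLASSES:
            raise ValueError(
                f"unknown road class {self.road_class!r}; expected one of {ROAD_CLASSES}"
            )
        if len(self.geometry) < 2:
            raise ValueError("segment geometry needs at least two points")
        if self.length_m <= 0:
            raise ValueError("segment length must be > 0")

    @property
    def length_m(self) -> float:
        return LineString(self.geometry).length


@dataclass(frozen=True)
class SpeedModel:
    """Free-flow speed in km/h per road class."""

    speeds_kmh: Mapping[str, float] = field(
        default_factory=lambda: {
            "expressway": 80.0,
            "main": 60.0,
            "secondary": 40.0,
            "local": 30.0,
        }
    )

    def __post_init__(self) -> None:
        missing = set(ROAD_CLASSES) - set(self.speeds_kmh)
        if missing:
            raise ValueError(f"missing speed for road class(es): {sorted(missing)}")
        if any(v <= 0 for v in self.speeds_kmh.values()):
            raise ValueError("all speeds must be > 0")

    def minutes(self, length_m: float, road_class: str) -> float:
        """Traversal time of a segment: metres / (km/h * 1000/60)."""
        metres_per_min = self.speeds_kmh[road_class] * 1000.0 / 60.0
        return length_m / metres_per_min


@dataclass(frozen=True)
class TravelTimeMatrix:
    """Region-by-facility drive times in minutes (``inf`` = unreachable)."""

    origin_ids: tuple[str, ...]
    destination_ids: tuple[str, ...]
    times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        expected = (len(self.origin_ids), len(self.destination_ids))
        if times.shape != expected:
            raise ValueError(f"times shape {times.shape}, expected {expected}")
        if np.any(np.isnan(times)) or np.any(times < 0):
            raise ValueError("travel times must be non-negative and not NaN")
        object.__setattr__(self, "times", times)

    def time(self, origin_id: str, destination_id: str) -> float:
        i = self.origin_ids.index(origin_id)
        j = self.destination_ids.index(destination_id)
        return float(self.times[i, j])


def weighted_centroid(
    points: Sequence[tuple[float, float]], weights: Sequence[float] | None = None
) -> tuple[float, float]:
    """Demand-weighted centroid: the weight-averaged coordinate.

    With equal (or omitted) weights this is the plain centroid. All-zero
    weights leave the centroid undefined and raise.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("at least one point is required")
    w = (
        np.ones(pts.shape[0])
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    if w.shape[0] != pts.shape[0]:
        raise ValueError("one weight per point required")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("all weights are zero; centroid undefined")
    x, y = (w @ pts) / total
    return (float(x), float(y))


def _node_key(coord: Sequence[float]) -> tuple[float, float]:
    return (
        round(float(coord[0]), _SNAP_DECIMALS),
        round(float(coord[1]), _SNAP_DECIMALS),
    )


def build_network(
    roads: Sequence[RoadSegment], speeds: SpeedModel | None = None
) -> nx.Graph:
    """Build the undirected travel graph from road segments.

    Nodes are segment endpoints (coordinates snapped to micro-metre
    precision so touching segments connect); each edge carries its cost in
    ``minutes`` plus the metric ``length_m`` and ``road_class``. Where two
    segments join the same node pair, the faster one wins.
    """
    speeds = speeds or SpeedModel()
    g = nx.Graph()
    for seg in roads:
        coords = [_node_key(c) for c in seg.geometry]
        for a, b in zip(coords[:-1], coords[1:]):
            if a == b:
                continue
            length = float(np.hypot(b[0] - a[0], b[1] - a[1]))
            cost = speeds.minutes(length, seg.road_class)
            if g.has_edge(a, b) and g[a][b]["minutes"] <= cost:
                continue
            g.add_edge(a, b, minutes=cost, length_m=length, road_class=seg.road_class)
    return g


def _nearest_node(g: nx.Graph, point: tuple[float, float]) -> tuple[float, float]:
    nodes = np.array(list(g.nodes))
    d2 = ((nodes - np.asarray(point, dtype=float)) ** 2).sum(axis=1)
    return tuple(nodes[int(np.argmin(d2))])


def travel_time_matrix(
    graph: nx.Graph,
    origins: Mapping[str, tuple[float, float]],
    destinations: Mapping[str, tuple[float, float]],
) -> TravelTimeMatrix:
    """Least-cost drive times from every origin to every destination.

    Each point is attached to its nearest network node and a Dijkstra
    shortest-path tree is grown from each destination node (typically far
    fewer destinations than origins). Pairs with no connecting path get
    ``inf``.
    """
    if len(graph) == 0:
        raise ValueError("empty road network")
    origin_ids = tuple(origins)
    dest_ids = tuple(destinations)
    origin_nodes = {oid: _nearest_node(graph, origins[oid]) for oid in origin_ids}
    dest_nodes = {did: _nearest_node(graph, destinations[did]) for did in dest_ids}

    times = np.full((len(origin_ids), len(dest_ids)), np.inf)
    for j, did in enumerate(dest_ids):
        lengths = nx.single_source_dijkstra_path_length(
            graph, dest_nodes[did], weight="minutes"
        )
        for i, oid in enumerate(origin_ids):
            t = lengths.get(origin_nodes[oid])
            if t is not None:
                times[i, j] = t
    return TravelTimeMatrix(origin_ids, dest_ids, times)


def closest_facility_distance(ttm: TravelTimeMatrix) -> dict[str, float]:
    """Per-region minutes to the closest facility (the row minimum).

    The closest-facility distance (CFD) is the external yardstick used to
    validate accessibility scores. Regions reaching no facility at all map
    to ``inf``.
    """
    mins = ttm.times.min(axis=1)
    return {oid: float(m) for oid, m in zip(ttm.origin_ids, mins)}
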