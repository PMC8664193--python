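"""Travel-time road graph: construction from line geometry, facility and
centroid snapping, and population-weighted centroids.

The graph is undirected with symmetric travel times. Edge travel time is
derived from segment length and the posted speed limit:

    travel_min = (length_m / 1000) / speed_kmh * 60

Coordinates are planar meters; inputs are assumed pre-projected (study-area
scale, no geodesic math).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import shapely
from shapely.geometry import Polygon

AMBULANCE_STATION = "ambulance_station"
EMERGENCY_DEPARTMENT = "emergency_department"
FACILITY_KINDS = (AMBULANCE_STATION, EMERGENCY_DEPARTMENT)

#: default tolerance (meters) within which line endpoints are merged into
#: one junction when building the graph
DEFAULT_MERGE_TOLERANCE = 1.0


def edge_travel_time(length_m: float, speed_kmh: float) -> float:
    """Travel time in minutes for a road segment.

    Parameters
    ----------
    length_m : segment length in meters (``>= 0``).
    speed_kmh : speed limit in km/h (``> 0``).
    """
    if speed_kmh <= 0:
        raise ValueError(f"speed_kmh must be positive, got {speed_kmh}")
    if length_m < 0:
        raise ValueError(f"length_m must be nonnegative, got {length_m}")
    return (length_m / 1000.0) / speed_kmh * 60.0


@dataclass(frozen=True)
class Facility:
    """An ambulance station or hospital emergency department.

    ``snapped_node`` is filled in once the facility has been relocated to
    the closest junction of a road network, so that drive times are always
    measured along whole segments.
    """

    facility_id: str
    kind: str
    location: tuple[float, float]
    snapped_node: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in FACILITY_KINDS:
            raise ValueError(f"unknown facility kind {self.kind!r}")

    def snapped(self, network: "RoadNetwork") -> "Facility":
        return replace(self, snapped_node=snap_to_junction(self.location, network))


@dataclass(frozen=True)
class WeightedCentroid:
    """Demand point of an analysis area.

    ``weighted`` is True when the point is the population-weighted mean of
    grid-cell centers; False when no populated cell intersected the area and
    the plain geometric centroid was used instead.
    """

    area_id: str
    point: tuple[float, float]
    weighted: bool
    snapped_node: int | None = None


class RoadNetwork:
    """Undirected routed graph over junction nodes.

    Nodes carry planar coordinates (attribute ``pos``); edges carry
    ``length_m``, ``speed_kmh`` and the derived ``travel_min`` used as the
    routing weight. Edges originating from a border buffer (included to
    avoid border effects but not reported on) carry ``buffer=True``.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()
        self._node_cache: tuple[np.ndarray, np.ndarray] | None = None

    # -- construction -------------------------------------------------

    def add_node(self, node_id: int, x: float, y: float, buffer: bool = False) -> None:
        self.graph.add_node(node_id, pos=(float(x), float(y)), buffer=buffer)
        self._node_cache = None

    def add_edge(
        self,
        a: int,
        b: int,
        length_m: float,
        speed_kmh: float,
        buffer: bool = False,
    ) -> None:
        """Add (or deduplicate) an edge; parallel duplicates keep the
        smaller travel time."""
        if a == b:
            raise ValueError(f"self-loop at node {a}")
        t = edge_travel_time(length_m, speed_kmh)
        if length_m <= 0:
            raise ValueError(f"edge ({a},{b}) has nonpositive length {length_m}")
        if self.graph.has_edge(a, b):
            if self.graph.edges[a, b]["travel_min"] <= t:
                return
        self.graph.add_edge(
            a, b, length_m=float(length_m), speed_kmh=float(speed_kmh),
            travel_min=t, buffer=buffer,
        )

    # -- views ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def position(self, node_id: int) -> tuple[float, float]:
        return self.graph.nodes[node_id]["pos"]

    def node_array(self) -> tuple[np.ndarray, np.ndarray]:
        """(node ids, coordinates) as parallel arrays, cached."""
        if self._node_cache is None:
            ids = np.array(sorted(self.graph.nodes), dtype=object)
            coords = np.array([self.graph.nodes[i]["pos"] for i in ids], dtype=float)
            self._node_cache = (ids, coords)
        return self._node_cache

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)

    def edge_records(self) -> list[dict]:
        out = []
        for a, b, data in self.graph.edges(data=True):
            out.append({"a": a, "b": b, **data})
        return out


def snap_to_junction(point: Sequence[float], network: RoadNetwork) -> int:
    """Closest junction to ``point`` by Euclidean distance.

    Exact distance ties are broken by the lowest node id so results are
    reproducible run to run.
    """
    if network.n_nodes == 0:
        raise ValueError("cannot snap to an empty network")
    ids, coords = network.node_array()
    d2 = np.sum((coords - np.asarray(point, dtype=float)) ** 2, axis=1)
    dmin = d2.min()
    # candidates within floating slack of the minimum; pick lowest id
    tied = ids[d2 <= dmin + 1e-9 * (1.0 + dmin)]
    return min(tied)


def weighted_centroid(
    area_id: str,
    polygon: Polygon,
    cells: Iterable[tuple[tuple[float, float], float]],
) -> WeightedCentroid:
    """Population-weighted centroid of an area.

    ``cells`` are (center, count) pairs of a population grid. The centroid
    is the count-weighted mean of the centers of populated cells covered by
    the polygon; when no populated cell intersects the area the geometric
    centroid is returned with ``weighted=False``.
    """
    if polygon.area <= 0:
        raise ValueError(f"area {area_id}: degenerate polygon with zero area")
    pts = []
    wts = []
    for (x, y), count in cells:
        if count > 0 and shapely.intersects_xy(polygon, x, y):
            pts.append((x, y))
            wts.append(count)
    if not pts:
        c = polygon.centroid
        return WeightedCentroid(area_id, (c.x, c.y), weighted=False)
    pts_arr = np.asarray(pts, dtype=float)
    wts_arr = np.asarray(wts, dtype=float)
    mean = (pts_arr * wts_arr[:, None]).sum(axis=0) / wts_arr.sum()
    return WeightedCentroid(area_id, (float(mean[0]), float(mean[1])), weighted=True)


def build_network(
    line_features: Iterable[Mapping],
    buffer_features: Iterable[Mapping] | None = None,
    merge_tolerance: float = DEFAULT_MERGE_TOLERANCE,
) -> RoadNetwork:
    """Build a :class:`RoadNetwork` from GeoJSON-style LineString features.

    Each feature needs ``properties.length_m`` and ``properties.speed_kmh``;
    endpoints within ``merge_tolerance`` meters collapse into one junction.
    Features may carry explicit ``node_a``/``node_b`` ids (as written by the
    synthetic generator), which are then preserved verbatim. Duplicate edges
    keep the minimum travel time. ``buffer_features`` are border-buffer roads:
    routable, but flagged so their surroundings are excluded from reporting.
    """
    net = RoadNetwork()
    key_to_node: dict[tuple[int, int], int] = {}
    next_id = 0

    def node_for(x: float, y: float, explicit: int | None, buffer: bool) -> int:
        nonlocal next_id
        key = (round(x / merge_tolerance), round(y / merge_tolerance))
        if explicit is not None:
            nid = explicit
        elif key in key_to_node:
            return key_to_node[key]
        else:
            while next_id in net.graph:
                next_id += 1
            nid = next_id
        if key not in key_to_node:
            key_to_node[key] = nid
        if nid not in net.graph:
            net.add_node(nid, x, y, buffer=buffer)
        return key_to_node.get(key, nid)

    def ingest(features: Iterable[Mapping], buffer: bool) -> None:
        for i, feat in enumerate(features):
            geom = feat.get("geometry", {})
            if geom.get("type") != "LineString":
                raise ValueError(f"feature {i}: expected LineString, got {geom.get('type')}")
            props = feat.get("properties", {}) or {}
            if "length_m" not in props or "speed_kmh" not in props:
                fid = props.get("id", i)
                raise ValueError(
                    f"feature {fid}: missing required 'length_m'/'speed_kmh' properties"
                )
            coords = geom["coordinates"]
            (x0, y0), (x1, y1) = coords[0], coords[-1]
            a = node_for(x0, y0, props.get("node_a"), buffer)
            b = node_for(x1, y1, props.get("node_b"), buffer)
            if a == b:
                continue  # segment collapsed by endpoint merging
            net.add_edge(a, b, props["length_m"], props["speed_kmh"], buffer=buffer)

    ingest(line_features, buffer=False)
    if buffer_features is not None:
        ingest(buffer_features, buffer=True)
    return net


def euclidean(p: Sequence[float], q: Sequence[float]) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])
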