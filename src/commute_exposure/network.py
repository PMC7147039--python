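"""Classed road network, snapping and minimum-weight routing.

The network is an undirected planar graph of road arcs.  Each arc carries a
polyline geometry, a length, one of four road classes (main, residential,
footpath, minor), amenity flags and — once a cost table has been applied — a
per-meter impedance multiplier.

Routing is Dijkstra with a deterministic tie-break: among equal-weight paths
the lexicographically smallest node-id sequence wins.  Distance mode
(arc weight = length) produces shortest network routes (SNR); cost mode
(arc weight = length x cost_per_m) produces weighted network routes (WNR).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import networkx as nx
import numpy as np
from shapely import STRtree
from shapely.geometry import LineString, Point

from .config import ROAD_CLASSES, TO_SCHOOL
from .errors import ConfigError, DataError, RoutingError, SnapError
from .routes import SNR, RouteRecord

DISTANCE = "distance"
COST = "cost"


@dataclass
class RoadArc:
    """One undirected road centreline segment."""

    arc_id: int
    from_node: int
    to_node: int
    geometry: LineString
    road_class: str
    has_traffic_light: bool = False
    has_outlet: bool = False
    cost_per_m: float | None = None

    def __post_init__(self) -> None:
        if self.road_class not in ROAD_CLASSES:
            raise DataError(
                f"arc {self.arc_id}: road class {self.road_class!r} not one of "
                f"{ROAD_CLASSES}")
        if self.geometry.length <= 0:
            raise DataError(f"arc {self.arc_id} has zero length")

    @property
    def length_m(self) -> float:
        return self.geometry.length


class RoadNetwork:
    """Undirected classed road graph with a spatial index over arcs."""

    def __init__(self, nodes: dict[int, tuple[float, float]], arcs: list[RoadArc]):
        if not arcs:
            raise DataError("network has no arcs")
        self.nodes = dict(nodes)
        self.arcs = list(arcs)
        self.graph = nx.Graph()
        for nid, xy in self.nodes.items():
            self.graph.add_node(nid, pos=xy)
        self._arc_by_edge: dict[tuple[int, int], RoadArc] = {}
        for arc in self.arcs:
            key = (min(arc.from_node, arc.to_node), max(arc.from_node, arc.to_node))
            self.graph.add_edge(arc.from_node, arc.to_node, arc=arc)
            self._arc_by_edge[key] = arc
        self._node_ids = np.array(sorted(self.nodes))
        self._node_xy = np.array([self.nodes[i] for i in self._node_ids], float)
        self._tree = STRtree([a.geometry for a in self.arcs])
        # adjacency with sorted neighbours for deterministic tie-breaking
        self._adj: dict[int, list[int]] = {
            n: sorted(self.graph.neighbors(n)) for n in self.graph.nodes
        }

    # -- basic queries -----------------------------------------------------

    def arc(self, u: int, v: int) -> RoadArc:
        return self._arc_by_edge[(min(u, v), max(u, v))]

    @property
    def arc_tree(self) -> STRtree:
        return self._tree

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def total_length_by_class(self) -> dict[str, float]:
        out = {c: 0.0 for c in ROAD_CLASSES}
        for a in self.arcs:
            out[a.road_class] += a.length_m
        return out

    # -- snapping ----------------------------------------------------------

    def snap(self, point: Point, max_distance: float = 500.0) -> tuple[int, float]:
        """Nearest network node to ``point``; ties go to the smallest node id.

        Raises SnapError when the nearest node is farther than ``max_distance``.
        """
        d = np.hypot(self._node_xy[:, 0] - point.x, self._node_xy[:, 1] - point.y)
        dmin = d.min()
        if dmin > max_distance:
            raise SnapError(
                f"point ({point.x:.1f}, {point.y:.1f}) is {dmin:.1f} m from the "
                f"nearest network node (max {max_distance} m)")
        # smallest id among ties (within float exactness)
        nid = int(self._node_ids[d == dmin].min())
        return nid, float(dmin)

    # -- routing -----------------------------------------------------------

    def _weight_fn(self, weight: str):
        if weight == DISTANCE:
            return lambda arc: arc.length_m
        if weight == COST:
            def w(arc: RoadArc) -> float:
                if arc.cost_per_m is None:
                    raise ConfigError(
                        f"arc {arc.arc_id} has no cost; apply a cost table first")
                return arc.length_m * arc.cost_per_m
            return w
        raise ConfigError(f"unknown weight mode {weight!r}")

    def shortest_path_nodes(self, origin: int, dest: int,
                            weight: str = DISTANCE) -> tuple[list[int], float]:
        """Minimum-weight simple path as a node list, plus its total weight.

        Dijkstra with heap entries ordered by (weight, node sequence), so the
        returned path is the lexicographically smallest among optima.
        """
        if origin not in self.graph or dest not in self.graph:
            raise RoutingError(f"origin {origin} or destination {dest} not in network")
        wfn = self._weight_fn(weight)
        heap: list[tuple[float, tuple[int, ...]]] = [(0.0, (origin,))]
        done: set[int] = set()
        while heap:
            dist, path = heapq.heappop(heap)
            node = path[-1]
            if node in done:
                continue
            done.add(node)
            if node == dest:
                return list(path), dist
            for nbr in self._adj[node]:
                if nbr in done or nbr in path:
                    continue
                w = wfn(self.arc(node, nbr))
                heapq.heappush(heap, (dist + w, path + (nbr,)))
        raise RoutingError(f"no path between nodes {origin} and {dest}")

    def path_geometry(self, node_path: list[int]) -> LineString:
        """Concatenate arc polylines along a node path (orientation-corrected)."""
        coords: list[tuple[float, float]] = []
        for u, v in zip(node_path[:-1], node_path[1:]):
            pts = list(self.arc(u, v).geometry.coords)
            if Point(pts[0]).distance(Point(self.nodes[u])) > \
                    Point(pts[-1]).distance(Point(self.nodes[u])):
                pts = pts[::-1]
            if coords:
                pts = pts[1:]
            coords.extend(pts)
        return LineString(coords)

    def shortest_route(self, origin: int, dest: int, weight: str = DISTANCE,
                       participant_id: str = "", direction: str = TO_SCHOOL,
                       source: str = SNR) -> RouteRecord:
        node_path, total = self.shortest_path_nodes(origin, dest, weight)
        return RouteRecord(
            participant_id=participant_id,
            direction=direction,
            source=source,
            geometry=self.path_geometry(node_path),
            node_path=node_path,
            total_weight=total,
        )


@dataclass
class HomeSchoolPair:
    """A participant's home point and assigned school."""

    participant_id: str
    home: Point
    school_id: str
    school: Point
    home_node: int | None = None
    school_node: int | None = None


def _with_stubs(geom: LineString, start: Point, end: Point) -> LineString:
    """Prepend/append straight anchor stubs, skipping zero-length duplicates."""
    coords = list(geom.coords)
    if Point(coords[0]).distance(start) > 1e-9:
        coords = [(start.x, start.y)] + coords
    if Point(coords[-1]).distance(end) > 1e-9:
        coords = coords + [(end.x, end.y)]
    return LineString(coords)


def route_for_pair(network: RoadNetwork, pair: HomeSchoolPair, direction: str,
                   weight: str = DISTANCE, source: str = SNR,
                   snap_max: float = 500.0) -> RouteRecord:
    """Route one home-school pair in one direction, with anchor stubs.

    The geometry runs origin -> destination in the direction of travel:
    home -> school for ``to_school``, school -> home for ``home``.
    """
    if pair.home_node is None:
        pair.home_node, _ = network.snap(pair.home, snap_max)
    if pair.school_node is None:
        pair.school_node, _ = network.snap(pair.school, snap_max)
    if direction == TO_SCHOOL:
        o, d, start, end = pair.home_node, pair.school_node, pair.home, pair.school
    else:
        o, d, start, end = pair.school_node, pair.home_node, pair.school, pair.home
    rec = network.shortest_route(o, d, weight=weight,
                                 participant_id=pair.participant_id,
                                 direction=direction, source=source)
    rec.geometry = _with_stubs(rec.geometry, start, end)
    return rec


def generate_snr(network: RoadNetwork, pairs: list[HomeSchoolPair],
                 directions: tuple[str, ...] = ("to_school", "home"),
                 snap_max: float = 500.0) -> list[RouteRecord]:
    """Distance-shortest network route per pair per direction (source=SNR)."""
    out = []
    for pair in pairs:
        for direction in directions:
            out.append(route_for_pair(network, pair, direction,
                                      weight=DISTANCE, source=SNR,
                                      snap_max=snap_max))
    return out
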