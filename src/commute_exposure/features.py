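"""Built-environment characteristics along a route.

For every route (GPS trace, SNR or WNR) the method computes one
characteristic vector: route length, percentage of the route near bluespace
and woodland, percentage along each of the four road classes, and counts of
traffic lights, pedestrian crossings, commute-hour road accidents and food
outlets within fixed Euclidean buffers.  These are the covariates of the
route-choice model and the exposure measures of the validation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

from .config import DEFAULT_WINDOWS, ROAD_CLASSES, FeatureConfig, window_of
from .errors import ConfigError
from .network import RoadNetwork
from .routes import RouteRecord


@dataclass
class AmenityLayers:
    """Point and polygon layers of the study area (planar meters)."""

    traffic_lights: list[Point] = field(default_factory=list)
    outlets: list[Point] = field(default_factory=list)
    #: (point, timestamp) pairs; filtered to commute hours when counted
    accidents: list[tuple[Point, datetime]] = field(default_factory=list)
    pedestrian_crossings: list[Point] = field(default_factory=list)
    bluespace: list[Polygon] = field(default_factory=list)
    woodland: list[Polygon] = field(default_factory=list)
    buildings: list[Polygon] = field(default_factory=list)


@dataclass
class RouteFeatures:
    """The characteristic vector for one route."""

    participant_id: str
    direction: str
    source: str
    length_km: float
    pct_bluespace: float
    pct_woodland: float
    pct_main: float
    pct_residential: float
    pct_footpath: float
    pct_minor: float
    n_traffic_lights: int
    n_accidents: int
    n_outlets: int
    n_crossings: int

    #: covariate columns (metadata excluded)
    NUMERIC: tuple = ("length_km", "pct_bluespace", "pct_woodland", "pct_main",
                      "pct_residential", "pct_footpath", "pct_minor",
                      "n_traffic_lights", "n_accidents", "n_outlets",
                      "n_crossings")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("participant_id", "direction", "source") + self.NUMERIC}


def pct_within(route: LineString, polygons: list[Polygon], buffer: float) -> float:
    """Percentage of the route length lying within ``buffer`` m of the polygons."""
    if buffer <= 0:
        raise ConfigError("buffer must be positive")
    if not polygons:
        return 0.0
    zone = unary_union([p.buffer(buffer) for p in polygons])
    inter = route.intersection(zone)
    return 100.0 * inter.length / route.length


def count_near(route: LineString, points: list, buffer: float,
               time_windows: dict | None = None) -> int:
    """Distinct points within ``buffer`` m of the route.

    ``points`` is a list of Point or (Point, timestamp).  When timestamps are
    present and ``time_windows`` is given, only points whose time of day falls
    in one of the windows are counted (the commute-hours accident rule).
    """
    if buffer <= 0:
        raise ConfigError("buffer must be positive")
    geoms = []
    for p in points:
        if isinstance(p, tuple):
            pt, ts = p
            if time_windows is not None and window_of(ts.time(), time_windows) is None:
                continue
            geoms.append(pt)
        else:
            geoms.append(p)
    if not geoms:
        return 0
    d = shapely.distance(np.array(geoms, dtype=object), route)
    return int((d <= buffer).sum())


def road_class_percentages(route: LineString, network: RoadNetwork,
                           tolerance: float = 25.0,
                           step: float = 5.0) -> dict[str, float]:
    """Share of route length per road class, by nearest-arc assignment.

    The route is walked in ``step``-meter increments; each increment is
    assigned the class of the nearest arc within ``tolerance``, or left
    unclassified beyond it (possible only for off-network GPS traces).
    Percentages are of total route length, so they sum to <= 100.
    """
    length = route.length
    edges = np.arange(0.0, length, step)
    edges = np.append(edges, length)
    seg_len = np.diff(edges)
    mids = (edges[:-1] + edges[1:]) / 2.0
    pts = shapely.line_interpolate_point(route, mids)
    idx_pairs = network.arc_tree.query_nearest(
        pts, max_distance=tolerance, all_matches=False)
    out = {c: 0.0 for c in ROAD_CLASSES}
    for pt_i, arc_i in zip(*idx_pairs):
        out[network.arcs[arc_i].road_class] += seg_len[pt_i]
    return {c: 100.0 * v / length for c, v in out.items()}


class FeatureExtractor:
    """Precomputes buffered layers once, then scores routes cheaply."""

    def __init__(self, network: RoadNetwork, layers: AmenityLayers,
                 config: FeatureConfig | None = None,
                 commute_windows: dict | None = None):
        self.network = network
        self.layers = layers
        self.config = config or FeatureConfig()
        self.config.validate()
        self.windows = commute_windows or DEFAULT_WINDOWS
        cfg = self.config
        self._blue_zone = (unary_union([p.buffer(cfg.bluespace_buffer)
                                        for p in layers.bluespace])
                           if layers.bluespace else None)
        self._wood_zone = (unary_union([p.buffer(cfg.woodland_buffer)
                                        for p in layers.woodland])
                           if layers.woodland else None)
        self._lights = np.array(layers.traffic_lights, dtype=object)
        self._crossings = np.array(layers.pedestrian_crossings, dtype=object)
        self._outlets = np.array(layers.outlets, dtype=object)
        acc = [(pt, ts) for pt, ts in layers.accidents
               if window_of(ts.time(), self.windows) is not None]
        self._accidents = np.array([pt for pt, _ in acc], dtype=object)

    def _pct_zone(self, route: LineString, zone) -> float:
        if zone is None:
            return 0.0
        return 100.0 * route.intersection(zone).length / route.length

    def _count(self, route: LineString, pts: np.ndarray, buffer: float) -> int:
        if pts.size == 0:
            return 0
        return int((shapely.distance(pts, route) <= buffer).sum())

    def features_for(self, route: RouteRecord) -> RouteFeatures:
        cfg = self.config
        geom = route.geometry
        classes = road_class_percentages(geom, self.network,
                                         tolerance=cfg.class_tolerance,
                                         step=cfg.class_step)
        return RouteFeatures(
            participant_id=route.participant_id,
            direction=route.direction,
            source=route.source,
            length_km=route.length_km,
            pct_bluespace=self._pct_zone(geom, self._blue_zone),
            pct_woodland=self._pct_zone(geom, self._wood_zone),
            pct_main=classes["main"],
            pct_residential=classes["residential"],
            pct_footpath=classes["footpath"],
            pct_minor=classes["minor"],
            n_traffic_lights=self._count(geom, self._lights, cfg.traffic_light_buffer),
            n_accidents=self._count(geom, self._accidents, cfg.accident_buffer),
            n_outlets=self._count(geom, self._outlets, cfg.outlet_buffer),
            n_crossings=self._count(geom, self._crossings, cfg.crossing_buffer),
        )

    def feature_frame(self, routes: list[RouteRecord]) -> pd.DataFrame:
        return pd.DataFrame([self.features_for(r).as_dict() for r in routes])


def features_for(route: RouteRecord, network: RoadNetwork, layers: AmenityLayers,
                 config: FeatureConfig | None = None) -> RouteFeatures:
    """One-shot convenience wrapper around FeatureExtractor."""
    return FeatureExtractor(network, layers, config).features_for(route)
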