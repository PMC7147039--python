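"""Synthetic study area and cohort generator.

Emulates everything the method consumes: a classed road network on a
perturbed grid, amenity point/polygon layers, home and school locations, and
walkers whose route choice follows a known ground-truth impedance table.
Each walker emits noisy timestamped GPS fixes on weekdays inside the
07:30-09:30 (to school) and 14:30-16:30 (home) windows, plus a configurable
fraction of decoy fixes (midday, inside buildings, near home, weekend) that
exercise every inclusion filter.

Because walkers follow a *known* weighted network, the full pipeline can be
validated end-to-end: the route-choice model should recover the sign pattern
of the ground-truth costs, and the calibrated weighted routes should overlap
the GPS traces far better than shortest network routes.

All geometry is planar meters; everything is deterministic given the seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, box

from .config import DEFAULT_WINDOWS, HOME, ROAD_CLASSES, TO_SCHOOL
from .errors import ConfigError, DataError
from .features import AmenityLayers
from .gps import GpsPoint, points_to_frame
from .network import HomeSchoolPair, RoadArc, RoadNetwork
from .weighting import CostTable, apply_costs, flag_arcs

#: a Monday inside the original data-collection window (Nov 2012 - Mar 2014)
BASE_MONDAY = datetime(2013, 1, 7)

DEFAULT_CLASS_MIX = {"main": 0.2, "residential": 0.45, "footpath": 0.2,
                     "minor": 0.15}


@dataclass
class TownSpec:
    """Parameters of the synthetic study area."""

    grid_rows: int = 8
    grid_cols: int = 8
    block_length: float = 100.0
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    n_traffic_lights: int = 12
    n_outlets: int = 15
    n_bluespace_polys: int = 3
    n_woodland_polys: int = 3
    n_buildings: int = 24
    n_accidents: int = 10
    n_crossings: int = 6
    n_homes: int = 20
    n_schools: int = 2
    seed: int = 0

    def validate(self) -> None:
        if set(self.class_mix) != set(ROAD_CLASSES):
            raise ConfigError(f"class_mix must cover exactly {ROAD_CLASSES}")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("class_mix proportions must sum to 1")
        counts = (self.n_traffic_lights, self.n_outlets, self.n_bluespace_polys,
                  self.n_woodland_polys, self.n_buildings, self.n_accidents,
                  self.n_crossings, self.n_homes, self.n_schools)
        if any(c < 0 for c in counts):
            raise ConfigError("all counts must be >= 0")
        if self.block_length <= 0:
            raise ConfigError("block_length must be positive")
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ConfigError("grid must be at least 2x2")


@dataclass
class WalkerSpec:
    """Parameters of the synthetic cohort."""

    n_walkers: int = 20
    ground_truth_costs: object = None   # CostTable or {direction: CostTable}
    gps_noise_sd: float = 5.0           # per-axis isotropic noise, meters
    #: lag-1 autocorrelation of the noise along a trace (GPS error drifts
    #: slowly, so consecutive fixes share most of their error)
    gps_noise_rho: float = 0.9
    fix_interval: float = 10.0          # seconds between fixes
    walk_speed: float = 1.4             # m/s; must stay below the 10 m/s rule
    p_to_school: float = 0.9
    p_home: float = 0.9
    decoy_fraction: float = 0.1
    #: walker-level preference heterogeneity: each walker's cost-table slots
    #: are multiplied by independent exp(N(0, preference_sd)) factors, so
    #: route choice is probabilistic at cohort level (0 = every walker
    #: follows ground_truth_costs exactly)
    preference_sd: float = 0.25
    #: idiosyncratic route-choice noise: each walker perceives every arc's
    #: cost multiplied by an independent exp(N(0, route_noise_sd)) factor
    #: (random-utility route choice); 0 = deterministic optimisation
    route_noise_sd: float = 0.3
    #: probability a trip is only partially recorded (late device fix
    #: acquisition / early cut-off), emulating the truncated traces of real
    #: commute GPS data; a partial trip records the chainage window
    #: [U(0, 0.2), U(0.85, 1.0)] of the path
    p_partial: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.walk_speed <= 0 or self.walk_speed >= 10:
            raise ConfigError("walk_speed must be in (0, 10) m/s so trips "
                              "classify as walking")
        if self.gps_noise_sd < 0:
            raise ConfigError("gps_noise_sd must be >= 0")
        if not 0 <= self.gps_noise_rho < 1:
            raise ConfigError("gps_noise_rho must be in [0, 1)")
        for p in (self.p_to_school, self.p_home):
            if not 0 <= p <= 1:
                raise ConfigError("trip probabilities must be in [0, 1]")
        if not 0 <= self.decoy_fraction < 1:
            raise ConfigError("decoy_fraction must be in [0, 1)")
        if self.preference_sd < 0:
            raise ConfigError("preference_sd must be >= 0")
        if self.route_noise_sd < 0:
            raise ConfigError("route_noise_sd must be >= 0")
        if not 0 <= self.p_partial <= 1:
            raise ConfigError("p_partial must be in [0, 1]")
        if self.fix_interval <= 0:
            raise ConfigError("fix_interval must be positive")

    def cost_table(self, direction: str) -> CostTable:
        gt = self.ground_truth_costs
        if gt is None:
            gt = CostTable.uniform()
        if isinstance(gt, dict):
            return gt[direction]
        return CostTable.from_slots(gt.slot_values(), direction)


@dataclass
class SchoolSite:
    school_id: str
    point: Point
    footprint: Polygon


@dataclass
class Town:
    """A generated study area."""

    spec: TownSpec
    network: RoadNetwork
    layers: AmenityLayers
    pairs: list[HomeSchoolPair]
    schools: dict[str, SchoolSite]

    @property
    def school_footprints(self) -> dict[str, Polygon]:
        return {sid: s.footprint for sid, s in self.schools.items()}

    @property
    def school_points(self) -> dict[str, Point]:
        return {sid: s.point for sid, s in self.schools.items()}


@dataclass
class TrueRoute:
    """Ground-truth minimum-cost path a synthetic walker actually followed."""

    participant_id: str
    direction: str
    geometry: LineString
    node_path: list


@dataclass
class SyntheticCohort:
    points: list[GpsPoint]
    true_routes: dict[tuple[str, str], TrueRoute]
    spec: WalkerSpec

    def points_frame(self) -> pd.DataFrame:
        return points_to_frame(self.points)


def _perp_offset(line: LineString, dist: float, offset: float) -> Point:
    """Point at chainage ``dist`` displaced ``offset`` m perpendicular."""
    p = line.interpolate(dist)
    q = line.interpolate(min(dist + 1.0, line.length))
    dx, dy = q.x - p.x, q.y - p.y
    norm = math.hypot(dx, dy) or 1.0
    return Point(p.x - dy / norm * offset, p.y + dx / norm * offset)


def generate_town(spec: TownSpec | None = None, max_retries: int = 5) -> Town:
    """Build the road network, amenity layers and home-school pairs."""
    spec = spec or TownSpec()
    spec.validate()
    last_err = None
    for attempt in range(max_retries):
        try:
            return _generate_town_once(spec, spec.seed + attempt * 7919)
        except DataError as err:   # disconnected / infeasible draw: retry
            last_err = err
    raise DataError(f"town generation failed after {max_retries} attempts: {last_err}")


def _generate_town_once(spec: TownSpec, seed: int) -> Town:
    rng = np.random.default_rng(seed)
    L = spec.block_length
    rows, cols = spec.grid_rows, spec.grid_cols

    # perturbed grid nodes; jitter bounded by 0.2 * block_length per axis
    nodes: dict[int, tuple[float, float]] = {}
    for i in range(rows):
        for j in range(cols):
            jit = rng.uniform(-0.2 * L, 0.2 * L, size=2)
            nodes[i * cols + j] = (j * L + jit[0], i * L + jit[1])

    classes = list(ROAD_CLASSES)
    probs = np.array([spec.class_mix[c] for c in classes])
    arcs: list[RoadArc] = []
    arc_id = 0
    for i in range(rows):
        for j in range(cols):
            nid = i * cols + j
            for ni, nj in ((i, j + 1), (i + 1, j)):
                if ni >= rows or nj >= cols:
                    continue
                other = ni * cols + nj
                geom = LineString([nodes[nid], nodes[other]])
                arcs.append(RoadArc(arc_id, nid, other, geom,
                                    str(rng.choice(classes, p=probs))))
                arc_id += 1
    network = RoadNetwork(nodes, arcs)
    if not network.is_connected():
        raise DataError("generated network is disconnected")

    def random_point_near_arc(max_offset: float) -> Point:
        arc = arcs[int(rng.integers(len(arcs)))]
        d = rng.uniform(0, arc.geometry.length)
        off = rng.uniform(-max_offset, max_offset)
        return _perp_offset(arc.geometry, d, off)

    def random_square(side: float, offset: float) -> Polygon:
        arc = arcs[int(rng.integers(len(arcs)))]
        d = rng.uniform(0, arc.geometry.length)
        c = _perp_offset(arc.geometry, d, offset * (1 if rng.random() < 0.5 else -1))
        return box(c.x - side / 2, c.y - side / 2, c.x + side / 2, c.y + side / 2)

    light_nodes = rng.choice(len(nodes), size=min(spec.n_traffic_lights, len(nodes)),
                             replace=False)
    layers = AmenityLayers(
        traffic_lights=[Point(nodes[int(n)]) for n in light_nodes],
        outlets=[random_point_near_arc(10.0) for _ in range(spec.n_outlets)],
        pedestrian_crossings=[random_point_near_arc(10.0)
                              for _ in range(spec.n_crossings)],
        bluespace=[random_square(40.0, 35.0) for _ in range(spec.n_bluespace_polys)],
        woodland=[random_square(40.0, 35.0) for _ in range(spec.n_woodland_polys)],
    )
    # accidents: commute-hour and midday timestamps mixed
    acc = []
    for _ in range(spec.n_accidents):
        pt = random_point_near_arc(10.0)
        hour = rng.choice([8, 12, 15], p=[0.4, 0.2, 0.4])
        ts = BASE_MONDAY + timedelta(days=int(rng.integers(0, 5)),
                                     hours=int(hour),
                                     minutes=int(rng.integers(0, 60)))
        acc.append((pt, ts))
    layers.accidents = acc

    # buildings sit in block interiors, clear of the (jittered) arcs
    cells = [(i, j) for i in range(rows - 1) for j in range(cols - 1)]
    rng.shuffle(cells)
    buildings = []
    for i, j in cells[:spec.n_buildings]:
        cx = np.mean([nodes[a * cols + b][0]
                      for a in (i, i + 1) for b in (j, j + 1)])
        cy = np.mean([nodes[a * cols + b][1]
                      for a in (i, i + 1) for b in (j, j + 1)])
        side = 20.0
        buildings.append(box(cx - side / 2, cy - side / 2,
                             cx + side / 2, cy + side / 2))
    layers.buildings = buildings

    # schools at distinct nodes, homes at distinct nodes >= 2.5 blocks away
    if spec.n_homes and spec.n_schools:
        if spec.n_homes < 2 * spec.n_schools:
            raise ConfigError("need at least two homes per school")
        all_ids = list(nodes)
        school_nodes = [int(n) for n in
                        rng.choice(all_ids, size=spec.n_schools, replace=False)]
        schools = {}
        for k, sn in enumerate(school_nodes):
            pt = Point(nodes[sn])
            schools[f"S{k}"] = SchoolSite(
                f"S{k}", pt, box(pt.x - 15, pt.y - 15, pt.x + 15, pt.y + 15))
        school_xy = np.array([[s.point.x, s.point.y] for s in schools.values()])
        candidates = [n for n in all_ids if n not in school_nodes]
        rng.shuffle(candidates)
        # prefer homes >= 2.5 blocks from any school (non-trivial commutes),
        # relaxing the radius when the grid cannot host the cohort
        home_nodes: list[int] = []
        for min_blocks in (2.5, 2.0, 1.5, 1.0):
            home_nodes = []
            for n in candidates:
                d = np.hypot(school_xy[:, 0] - nodes[n][0],
                             school_xy[:, 1] - nodes[n][1])
                if d.min() >= min_blocks * L:
                    home_nodes.append(n)
                if len(home_nodes) == spec.n_homes:
                    break
            if len(home_nodes) == spec.n_homes:
                break
        if len(home_nodes) < spec.n_homes:
            raise DataError("could not place enough homes away from schools")
        sids = list(schools)
        pairs = []
        for k, hn in enumerate(home_nodes):
            home_pt = Point(nodes[hn])
            d = np.hypot(school_xy[:, 0] - home_pt.x, school_xy[:, 1] - home_pt.y)
            pairs.append(HomeSchoolPair(f"P{k:03d}", home_pt,
                                        sids[int(np.argmin(d))],
                                        schools[sids[int(np.argmin(d))]].point,
                                        home_node=hn))
        # guarantee every school serves at least two homes
        for sid in sids:
            while sum(p.school_id == sid for p in pairs) < 2:
                target = schools[sid].point
                movable = [p for p in pairs
                           if p.school_id != sid
                           and sum(q.school_id == p.school_id for q in pairs) > 2]
                if not movable:
                    raise DataError(f"cannot give school {sid} two homes")
                p = min(movable, key=lambda p: p.home.distance(target))
                p.school_id, p.school = sid, target
        for p in pairs:
            p.school_node, _ = network.snap(p.school)
    else:
        schools, pairs = {}, []

    return Town(spec, network, layers, pairs, schools)


# -- walkers ---------------------------------------------------------------


def _trip_timestamps(rng, direction: str, duration_s: float) -> datetime:
    """Weekday start datetime such that the whole trip fits its window."""
    lo, hi = DEFAULT_WINDOWS[direction]
    day = BASE_MONDAY + timedelta(days=int(rng.integers(0, 5)),
                                  weeks=int(rng.integers(0, 4)))
    span = (hi.hour * 60 + hi.minute - lo.hour * 60 - lo.minute) * 60
    slack = max(span - duration_s - 60, 0)
    start_offset = rng.uniform(0, slack)
    return day.replace(hour=lo.hour, minute=lo.minute) + \
        timedelta(seconds=float(start_offset))


def generate_walkers(town: Town, pairs: list[HomeSchoolPair] | None = None,
                     spec: WalkerSpec | None = None) -> SyntheticCohort:
    """Emit GPS fixes for walkers following ground-truth minimum-cost paths.

    Fixes are spaced ``walk_speed * fix_interval`` meters along the true path,
    displaced by isotropic Gaussian noise.  Fixes inside the school footprint
    or within 45 m of home are not emitted (they would be removed by the
    inclusion criteria anyway), so with zero noise every emitted commute fix
    survives filtering.  Decoy fixes — midday, inside a building, near home,
    weekend — are appended at ``decoy_fraction`` of the commute fix count.
    """
    spec = spec or WalkerSpec()
    spec.validate()
    pairs = pairs if pairs is not None else town.pairs
    if spec.n_walkers < len(pairs):
        pairs = pairs[:spec.n_walkers]
    rng = np.random.default_rng(spec.seed)
    network = flag_arcs(town.network, town.layers, buffer=25.0)

    points: list[GpsPoint] = []
    true_routes: dict[tuple[str, str], TrueRoute] = {}
    decoy_types = ["midday", "building", "home", "weekend"]

    # walker-level preference heterogeneity: one multiplicative factor per
    # cost slot per walker, shared across directions
    slot_names = list(ROAD_CLASSES) + ["traffic_light", "outlet"]
    pref: dict[str, np.ndarray] = {
        p.participant_id: (np.exp(rng.normal(0.0, spec.preference_sd,
                                             size=len(slot_names)))
                           if spec.preference_sd > 0
                           else np.ones(len(slot_names)))
        for p in pairs}
    n_arcs = len(network.arcs)
    arc_noise: dict[str, np.ndarray] = {
        p.participant_id: (np.exp(rng.normal(0.0, spec.route_noise_sd,
                                             size=n_arcs))
                           if spec.route_noise_sd > 0 else np.ones(n_arcs))
        for p in pairs}

    for direction, p_record in ((TO_SCHOOL, spec.p_to_school),
                                (HOME, spec.p_home)):
        central = spec.cost_table(direction).slot_values()
        for pair in pairs:
            if pair.home_node == pair.school_node:
                continue  # degenerate walker: skipped
            record = rng.random() < p_record
            if not record:
                continue
            slots = {s: central[s] * f for s, f in
                     zip(slot_names, pref[pair.participant_id])}
            apply_costs(network, CostTable.from_slots(slots, direction))
            for arc, f in zip(network.arcs, arc_noise[pair.participant_id]):
                arc.cost_per_m *= f
            if direction == TO_SCHOOL:
                o, d = pair.home_node, pair.school_node
            else:
                o, d = pair.school_node, pair.home_node
            node_path, _ = network.shortest_path_nodes(o, d, weight="cost")
            line = network.path_geometry(node_path)
            true_routes[(pair.participant_id, direction)] = TrueRoute(
                pair.participant_id, direction, line, node_path)

            duration = line.length / spec.walk_speed
            start = _trip_timestamps(rng, direction, duration)
            step = spec.walk_speed * spec.fix_interval
            fp = town.schools[pair.school_id].footprint
            # partial recording window (GPS cold start / early cut-off)
            lo_frac, hi_frac = 0.0, 1.0
            if rng.random() < spec.p_partial:
                lo_frac = rng.uniform(0.0, 0.2)
                hi_frac = rng.uniform(0.85, 1.0)
            commute: list[GpsPoint] = []
            err = np.zeros(2)  # AR(1) noise state, stationary sd gps_noise_sd
            rho = spec.gps_noise_rho
            innov_sd = spec.gps_noise_sd * math.sqrt(1.0 - rho * rho)
            first = True
            for k, dist in enumerate(np.arange(0.0, line.length + 1e-9, step)):
                if not lo_frac * line.length <= dist <= hi_frac * line.length:
                    continue
                pos = line.interpolate(min(dist, line.length))
                if pos.distance(pair.home) <= 45.0 or fp.contains(pos):
                    continue
                if spec.gps_noise_sd > 0:
                    if first:
                        err = rng.normal(0.0, spec.gps_noise_sd, size=2)
                        first = False
                    else:
                        err = rho * err + rng.normal(0.0, innov_sd, size=2)
                    noise = err
                else:
                    noise = np.zeros(2)
                ts = start + timedelta(seconds=k * spec.fix_interval)
                commute.append(GpsPoint(pair.participant_id, ts,
                                        pos.x + noise[0], pos.y + noise[1],
                                        label="commute"))
            points.extend(commute)

            n_decoys = int(round(spec.decoy_fraction * len(commute)))
            for k in range(n_decoys):
                kind = decoy_types[k % len(decoy_types)]
                if kind == "building" and not town.layers.buildings:
                    kind = "midday"
                if kind == "midday":
                    pos = line.interpolate(rng.uniform(0, line.length))
                    ts = start.replace(hour=11, minute=0) + \
                        timedelta(seconds=float(rng.uniform(0, 7200)))
                elif kind == "building":
                    b = town.layers.buildings[int(rng.integers(
                        len(town.layers.buildings)))]
                    pos = b.centroid
                    ts = start + timedelta(seconds=float(rng.uniform(0, 600)))
                elif kind == "home":
                    ang = rng.uniform(0, 2 * np.pi)
                    r = rng.uniform(5, 35)
                    pos = Point(pair.home.x + r * np.cos(ang),
                                pair.home.y + r * np.sin(ang))
                    ts = start + timedelta(seconds=float(rng.uniform(0, 600)))
                else:  # weekend: Saturday fix inside the window
                    pos = line.interpolate(rng.uniform(0, line.length))
                    sat = start + timedelta(days=5 - start.weekday())
                    ts = sat
                points.append(GpsPoint(pair.participant_id, ts, pos.x, pos.y,
                                       label=f"decoy_{kind}"))

    return SyntheticCohort(points, true_routes, spec)


def generate_cohort(town_spec: TownSpec | None = None,
                    walker_spec: WalkerSpec | None = None
                    ) -> tuple[Town, SyntheticCohort]:
    """Town + walkers in one call, sizing homes to the cohort."""
    town_spec = town_spec or TownSpec()
    walker_spec = walker_spec or WalkerSpec()
    if town_spec.n_homes < walker_spec.n_walkers:
        town_spec.n_homes = walker_spec.n_walkers
    town = generate_town(town_spec)
    return town, generate_walkers(town, town.pairs, walker_spec)
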