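"""Impedance cost tables, the weighted network, and WNR/WNE generation.

Odds ratios from the route-choice model inform per-arc impedance costs:
features over-represented along chosen routes (OR > 1) get a cost below 1
(attractive), under-represented features a cost above 1 (repellent).  Costs
act as per-meter multipliers, so the router minimises sum(length x cost).

Assignment order follows the method: every arc first receives its road-class
cost; arcs flagged for a traffic light within 25 m are then *reassigned* the
traffic-light cost; arcs flagged for a food outlet within 25 m are reassigned
the outlet cost last (reassignment replaces, it does not multiply).  An arc
carrying both flags therefore ends with the outlet cost by default.

The default tables are the published calibrated values:

==============  ====  ===========  ========  =====  =============  ======
direction       main  residential  footpath  minor  traffic light  outlet
==============  ====  ===========  ========  =====  =============  ======
to school       0.8   0.5          0.8       1.5    0.5            0.8
home            0.8   0.4          0.8       1.2    0.7            0.5
==============  ====  ===========  ========  =====  =============  ======
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
import yaml

from .config import DIRECTIONS, HOME, ROAD_CLASSES, TO_SCHOOL
from .errors import ConfigError, DataError
from .network import COST, HomeSchoolPair, RoadNetwork, route_for_pair
from .routes import WNR, RouteRecord

_SLOTS = ROAD_CLASSES + ("traffic_light", "outlet")


@dataclass(frozen=True)
class CostTable:
    """Per-road-class and per-flag impedance multipliers for one direction."""

    class_costs: dict[str, float]
    traffic_light_cost: float
    outlet_cost: float
    direction: str = TO_SCHOOL

    def __post_init__(self) -> None:
        missing = set(ROAD_CLASSES) - set(self.class_costs)
        if missing:
            raise ConfigError(f"cost table missing road classes: {sorted(missing)}")
        vals = list(self.class_costs.values()) + [self.traffic_light_cost,
                                                  self.outlet_cost]
        if any(v <= 0 for v in vals):
            raise ConfigError("all cost multipliers must be positive")
        if self.direction not in DIRECTIONS:
            raise ConfigError(f"unknown direction {self.direction!r}")

    def slot_values(self) -> dict[str, float]:
        d = dict(self.class_costs)
        d["traffic_light"] = self.traffic_light_cost
        d["outlet"] = self.outlet_cost
        return d

    @classmethod
    def from_slots(cls, slots: dict[str, float], direction: str) -> "CostTable":
        return cls(class_costs={c: slots[c] for c in ROAD_CLASSES},
                   traffic_light_cost=slots["traffic_light"],
                   outlet_cost=slots["outlet"], direction=direction)

    @classmethod
    def uniform(cls, value: float = 1.0, direction: str = TO_SCHOOL) -> "CostTable":
        return cls.from_slots({s: value for s in _SLOTS}, direction)


#: published calibrated cost tables (one per direction)
DEFAULT_COST_TABLES: dict[str, CostTable] = {
    TO_SCHOOL: CostTable(
        class_costs={"main": 0.8, "residential": 0.5, "footpath": 0.8, "minor": 1.5},
        traffic_light_cost=0.5, outlet_cost=0.8, direction=TO_SCHOOL),
    HOME: CostTable(
        class_costs={"main": 0.8, "residential": 0.4, "footpath": 0.8, "minor": 1.2},
        traffic_light_cost=0.7, outlet_cost=0.5, direction=HOME),
}


def cost_tables_to_yaml(tables: dict[str, CostTable], path: str | Path) -> None:
    data = {d: t.slot_values() for d, t in tables.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def cost_tables_from_yaml(path: str | Path) -> dict[str, CostTable]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return {d: CostTable.from_slots(slots, d) for d, slots in data.items()}


def or_to_cost(odds_ratio: float, lo: float = 0.1, hi: float = 10.0) -> float:
    """Seed an impedance cost from an odds ratio (cost = 1/OR, clipped).

    OR > 1 (feature over-represented on chosen routes) maps to cost < 1.
    """
    if odds_ratio <= 0:
        raise ConfigError("odds ratio must be positive")
    return float(np.clip(1.0 / odds_ratio, lo, hi))


# -- flagging and costing -------------------------------------------------


def flag_arcs(network: RoadNetwork, layers, buffer: float = 25.0) -> RoadNetwork:
    """Set has_traffic_light / has_outlet on arcs within ``buffer`` m of a
    respective point.  Mutates and returns the network; idempotent."""
    geoms = [a.geometry for a in network.arcs]
    for attr, points in (("has_traffic_light", layers.traffic_lights),
                         ("has_outlet", layers.outlets)):
        flags = np.zeros(len(geoms), dtype=bool)
        if points:
            pts = np.array(points, dtype=object)
            for i, g in enumerate(geoms):
                flags[i] = bool((shapely.distance(pts, g) <= buffer).any())
        for arc, f in zip(network.arcs, flags):
            setattr(arc, attr, bool(f))
    return network


def apply_costs(network: RoadNetwork, table: CostTable,
                flag_precedence: str = "outlet") -> RoadNetwork:
    """Assign cost_per_m to every arc from a cost table.

    Road-class costs go on first; traffic-light-flagged arcs are reassigned
    the traffic-light cost; outlet-flagged arcs are reassigned the outlet
    cost.  ``flag_precedence`` decides a both-flags arc: "outlet" (default,
    outlet reassigned last) or "traffic_light".
    """
    if flag_precedence not in ("outlet", "traffic_light"):
        raise ConfigError(f"unknown flag precedence {flag_precedence!r}")
    first, second = (("traffic_light", "outlet") if flag_precedence == "outlet"
                     else ("outlet", "traffic_light"))
    flag_cost = {"traffic_light": table.traffic_light_cost,
                 "outlet": table.outlet_cost}
    flag_attr = {"traffic_light": "has_traffic_light", "outlet": "has_outlet"}
    for arc in network.arcs:
        cost = table.class_costs[arc.road_class]
        for flag in (first, second):
            if getattr(arc, flag_attr[flag]):
                cost = flag_cost[flag]
        arc.cost_per_m = cost
    return network


def generate_wnr(network: RoadNetwork, pairs: list[HomeSchoolPair],
                 table: CostTable, snap_max: float = 500.0) -> list[RouteRecord]:
    """Minimum-cost route per pair for the table's direction (source=WNR).

    The network must already be flagged; costs are (re)applied here so the
    weighting always matches ``table``.
    """
    apply_costs(network, table)
    return [route_for_pair(network, p, table.direction, weight=COST,
                           source=WNR, snap_max=snap_max) for p in pairs]


def compute_wne(wnr: RouteRecord, outlets, buffer: float = 100.0) -> int:
    """Weighted network exposure: food outlets within ``buffer`` m of the WNR."""
    from .features import count_near
    return count_near(wnr.geometry, list(outlets), buffer)


# -- cost-table calibration ------------------------------------------------


@dataclass
class SearchSpec:
    """Finite candidate grids per cost slot for one direction."""

    grids: dict[str, list[float]]
    direction: str = TO_SCHOOL
    #: exhaustive evaluation above this many tables switches to a seeded
    #: random subsample
    max_tables: int = 2048
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(_SLOTS) - set(self.grids)
        if missing:
            raise ConfigError(f"search grids missing slots: {sorted(missing)}")
        for slot, g in self.grids.items():
            if not g or any(v <= 0 for v in g):
                raise ConfigError(f"grid for {slot} must be non-empty and positive")

    def tables(self) -> list[CostTable]:
        combos = list(itertools.product(*(self.grids[s] for s in _SLOTS)))
        if len(combos) > self.max_tables:
            rng = np.random.default_rng(self.seed)
            idx = rng.choice(len(combos), size=self.max_tables, replace=False)
            combos = [combos[i] for i in sorted(idx)]
        return [CostTable.from_slots(dict(zip(_SLOTS, c)), self.direction)
                for c in combos]

    @classmethod
    def seeded_from_ors(cls, odds_ratios: dict[str, float], direction: str,
                        spread: tuple[float, ...] = (1.0,),
                        **kw) -> "SearchSpec":
        """Grids centred on the 1/OR seeds (slots without an OR default to 1)."""
        grids = {}
        for slot in _SLOTS:
            seed_cost = or_to_cost(odds_ratios.get(slot, 1.0))
            cand = sorted({round(seed_cost * s, 4) for s in spread} | {1.0})
            grids[slot] = cand
        return cls(grids=grids, direction=direction, **kw)


def _table_distance_to_unity(table: CostTable) -> float:
    v = np.array(list(table.slot_values().values()))
    return float(np.sum((v - 1.0) ** 2))


def optimize_costs(network: RoadNetwork, pairs: list[HomeSchoolPair],
                   gps_routes: list[RouteRecord], spec: SearchSpec,
                   intersection_buffer: float = 50.0,
                   snap_max: float = 500.0):
    """Grid-search the cost table maximising mean WNR-GPS intersection.

    Scores every candidate table by the mean 50 m intersection percentage of
    its WNRs against the direction's GPS routes (mean over GPS routes, with a
    participant's WNR scored against each of their GPS routes).  Ties break
    toward the table closest to all-ones.  Returns (best_table, trace) where
    trace is a DataFrame of every evaluated table and its score.
    """
    import pandas as pd

    from .validation import intersection_pct

    gps = [r for r in gps_routes if r.direction == spec.direction]
    if not gps:
        raise DataError(f"no GPS routes for direction {spec.direction!r}")
    by_pid: dict[str, list[RouteRecord]] = {}
    for r in gps:
        by_pid.setdefault(r.participant_id, []).append(r)
    use_pairs = [p for p in pairs if p.participant_id in by_pid]
    if not use_pairs:
        raise DataError("no home-school pairs match the GPS routes")

    rows = []
    best = None
    for table in spec.tables():
        wnrs = generate_wnr(network, use_pairs, table, snap_max=snap_max)
        pcts = []
        for wnr in wnrs:
            for gr in by_pid[wnr.participant_id]:
                pcts.append(intersection_pct(wnr, gr, buffer=intersection_buffer)
                            .intersect_pct)
        score = float(np.mean(pcts))
        rows.append({**{f"cost_{s}": v for s, v in table.slot_values().items()},
                     "score": score})
        key = (score, -_table_distance_to_unity(table))
        if best is None or key > best[0]:
            best = (key, table)
    trace = pd.DataFrame(rows)
    return best[1], trace
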