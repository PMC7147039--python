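"""Study configuration: time windows, buffers and thresholds.

Every numeric constant of the method lives here so a run is auditable from
one place.  All distances are meters in a single planar metric coordinate
system; times are naive local timestamps.

Conventions fixed by the method:

* commute windows 07:30-09:30 (to school) and 14:30-16:30 (home), treated as
  closed intervals at minute resolution;
* a fix counts as "at home" when it is <= 40 m from the home point;
* a trip is walking when its mean speed (path length / elapsed time) is
  strictly below 10 m/s;
* trip outliers are fixes more than 100 m from every other fix of the trip;
* arcs are flagged for traffic lights / food outlets within 25 m;
* exposure buffers: bluespace 50 m, woodland 25 m, food outlets 100 m,
  traffic lights / accidents / crossings 25 m;
* route agreement uses a 50 m buffer around the GPS route.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import time
from pathlib import Path

import yaml

from .errors import ConfigError

TO_SCHOOL = "to_school"
HOME = "home"
DIRECTIONS = (TO_SCHOOL, HOME)

ROAD_CLASSES = ("main", "residential", "footpath", "minor")

#: Commute windows per direction, inclusive bounds at minute resolution.
DEFAULT_WINDOWS: dict[str, tuple[time, time]] = {
    TO_SCHOOL: (time(7, 30), time(9, 30)),
    HOME: (time(14, 30), time(16, 30)),
}


def window_of(t: time, windows: dict[str, tuple[time, time]] | None = None) -> str | None:
    """Return the direction whose commute window contains ``t`` (or None)."""
    windows = windows or DEFAULT_WINDOWS
    for direction, (lo, hi) in windows.items():
        if lo <= t <= hi:
            return direction
    return None


@dataclass
class GpsConfig:
    """Thresholds for the GPS filtering / trip-building workflow."""

    home_exclusion_m: float = 40.0
    walking_speed_max: float = 10.0   # m/s, strict upper bound
    outlier_threshold_m: float = 100.0
    min_trip_points: int = 2
    #: gap (seconds) splitting a window's fixes into separate runs
    max_gap_s: float = 600.0
    keep_all_runs: bool = False

    def validate(self) -> None:
        if min(self.home_exclusion_m, self.walking_speed_max,
               self.outlier_threshold_m, self.max_gap_s) <= 0:
            raise ConfigError("all GPS thresholds must be positive")
        if self.min_trip_points < 2:
            raise ConfigError("a trip needs at least two fixes to form a line")


@dataclass
class FeatureConfig:
    """Buffers (meters) for the built-environment characteristic vector."""

    bluespace_buffer: float = 50.0
    woodland_buffer: float = 25.0
    outlet_buffer: float = 100.0
    traffic_light_buffer: float = 25.0
    accident_buffer: float = 25.0
    crossing_buffer: float = 25.0
    #: tolerance for assigning (off-network) route length to a road class
    class_tolerance: float = 25.0
    #: chainage step for road-class assignment
    class_step: float = 5.0

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ConfigError(f"feature buffer {f.name} must be positive")


@dataclass
class RunConfig:
    """Full pipeline configuration (paths + every threshold)."""

    network: str = ""
    gps: str = ""
    homes: str = ""
    schools: str = ""
    layers_dir: str = ""
    out_dir: str = "out"
    gps_config: GpsConfig = field(default_factory=GpsConfig)
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    flag_buffer: float = 25.0
    intersection_buffer: float = 50.0
    snap_max_distance: float = 500.0
    stepwise_alpha: float = 0.05
    #: per-slot candidate grids for cost optimization; None -> fixed defaults
    cost_grids: dict | None = None
    #: fixed cost tables (direction -> slot -> value); used when grids absent
    cost_tables: dict | None = None
    seed: int = 0

    def validate(self) -> None:
        self.gps_config.validate()
        self.feature_config.validate()
        for name in ("flag_buffer", "intersection_buffer", "snap_max_distance",
                     "stepwise_alpha"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "gps_config" in d and isinstance(d["gps_config"], dict):
            d["gps_config"] = GpsConfig(**d["gps_config"])
        if "feature_config" in d and isinstance(d["feature_config"], dict):
            d["feature_config"] = FeatureConfig(**d["feature_config"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
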