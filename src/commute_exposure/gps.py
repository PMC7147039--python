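"""GPS point processing: inclusion filters, trip segmentation, walking
classification, outlier removal and route construction.

The workflow mirrors the three-stage criteria-based approach used to prepare
commute GPS data:

pre-processing (inclusion criteria)
    keep a fix only if it is (i) on a weekday, (ii) inside a commute window
    (07:30-09:30 or 14:30-16:30), (iii) outside the participant's school
    building footprint, (iv) more than 40 m from the participant's home
    location, and (v) outside every building footprint;

processing
    order fixes by timestamp, group them into trips (consecutive fixes of
    one participant on one day inside one window), label morning trips
    ``to_school`` and afternoon trips ``home``, and keep trips whose mean
    speed (path length / elapsed time) is strictly below 10 m/s;

post-processing
    iteratively drop fixes more than 100 m from every other fix of their
    trip, then build the route polyline with the home and school anchor
    points appended to the ends.

Points travel through these functions as a pandas DataFrame with columns
``participant_id, timestamp, x, y`` (plus any extra columns, which are
preserved).  Every rejected point is logged with the criterion it failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import LineString, Point, Polygon

from .config import DEFAULT_WINDOWS, GpsConfig, window_of
from .errors import DataError
from .routes import GPS, RouteRecord

POINT_COLUMNS = ["participant_id", "timestamp", "x", "y"]

#: rejection criteria, in the order they are applied
CRITERIA = ("bad_timestamp", "weekday", "commute_window", "school_footprint",
            "near_home", "building_footprint")


@dataclass(frozen=True)
class GpsPoint:
    """One timestamped GPS fix in planar meters."""

    participant_id: str
    timestamp: datetime
    x: float
    y: float
    #: provenance label used by the synthetic generator ("commute" for real data)
    label: str = "commute"


@dataclass
class Participant:
    """Home location and school assignment; both are required for inclusion."""

    participant_id: str
    home: Point
    school_id: str


@dataclass
class Trip:
    """Consecutive fixes of one participant, one day, one commute window."""

    participant_id: str
    date: object
    direction: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.frame["timestamp"].is_monotonic_increasing:
            self.frame = self.frame.sort_values("timestamp").reset_index(drop=True)

    @property
    def n_points(self) -> int:
        return len(self.frame)

    def path_length_m(self) -> float:
        dx = np.diff(self.frame["x"].to_numpy())
        dy = np.diff(self.frame["y"].to_numpy())
        return float(np.hypot(dx, dy).sum())

    def elapsed_s(self) -> float:
        ts = self.frame["timestamp"]
        return float((ts.iloc[-1] - ts.iloc[0]).total_seconds())

    @property
    def mean_speed(self) -> float:
        dt = self.elapsed_s()
        return float("inf") if dt <= 0 else self.path_length_m() / dt


def points_to_frame(points: list[GpsPoint]) -> pd.DataFrame:
    rows = [{"participant_id": p.participant_id, "timestamp": p.timestamp,
             "x": p.x, "y": p.y, "label": p.label} for p in points]
    df = pd.DataFrame(rows, columns=POINT_COLUMNS + ["label"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


# -- pre-processing --------------------------------------------------------


def filter_points(points: pd.DataFrame,
                  participants: dict[str, Participant],
                  buildings: list[Polygon],
                  school_footprints: dict[str, Polygon],
                  config: GpsConfig | None = None,
                  windows: dict | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the five inclusion criteria.

    Returns (kept, rejected); ``rejected`` carries a ``criterion`` column
    naming the first criterion each dropped point failed.  Points whose
    participant is unknown (no home/school) are excluded upstream and are not
    expected here; they are rejected with criterion ``no_participant``.
    """
    config = config or GpsConfig()
    windows = windows or DEFAULT_WINDOWS
    df = points.copy().reset_index(drop=True)
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    df["timestamp"] = ts
    reason = pd.Series(pd.NA, index=df.index, dtype="object")

    known = df["participant_id"].isin(participants.keys())
    reason[~known] = "no_participant"

    bad_ts = ts.isna() & reason.isna()
    reason[bad_ts] = "bad_timestamp"

    ok = reason.isna()
    weekday = ts.dt.weekday < 5
    reason[ok & ~weekday] = "weekday"

    ok = reason.isna()
    in_window = ts.dt.time.map(
        lambda t: (not pd.isna(t)) and window_of(t, windows) is not None)
    reason[ok & ~in_window] = "commute_window"

    # participant-specific geometry checks, vectorised per participant
    xs, ys = df["x"].to_numpy(float), df["y"].to_numpy(float)
    in_school = np.zeros(len(df), dtype=bool)
    near_home = np.zeros(len(df), dtype=bool)
    for pid, grp in df.groupby("participant_id", sort=False):
        part = participants.get(pid)
        if part is None:
            continue
        idx = grp.index.to_numpy()
        d_home = np.hypot(xs[idx] - part.home.x, ys[idx] - part.home.y)
        near_home[idx] = d_home <= config.home_exclusion_m
        fp = school_footprints.get(part.school_id)
        if fp is not None:
            from shapely import contains_xy
            in_school[idx] = contains_xy(fp, xs[idx], ys[idx])
    ok = reason.isna().to_numpy()
    reason[ok & in_school] = "school_footprint"
    ok = reason.isna().to_numpy()
    reason[ok & near_home] = "near_home"

    ok = reason.isna().to_numpy()
    if buildings and ok.any():
        from shapely import points as make_points
        tree = STRtree(buildings)
        pts = make_points(np.column_stack([xs, ys]))
        hit = np.zeros(len(df), dtype=bool)
        pairs = tree.query(pts, predicate="within")
        hit[np.unique(pairs[0])] = True
        reason[ok & hit] = "building_footprint"

    kept = df[reason.isna()].reset_index(drop=True)
    rejected = df[reason.notna()].copy()
    rejected["criterion"] = reason[reason.notna()]
    return kept, rejected.reset_index(drop=True)


# -- processing ------------------------------------------------------------


def _split_runs(frame: pd.DataFrame, max_gap_s: float) -> list[pd.DataFrame]:
    gaps = frame["timestamp"].diff().dt.total_seconds().fillna(0.0)
    run_id = (gaps > max_gap_s).cumsum()
    return [g.reset_index(drop=True) for _, g in frame.groupby(run_id, sort=True)]


def segment_trips(points: pd.DataFrame,
                  config: GpsConfig | None = None,
                  windows: dict | None = None,
                  anchors: dict[str, tuple[Point, Point]] | None = None) -> list[Trip]:
    """Group filtered points into trips: one per (participant, date, window).

    Within one window, fixes are split into runs wherever consecutive fixes
    are more than ``max_gap_s`` apart (extra non-commute journeys inside the
    window, removed manually in the original workflow, become separate runs).
    Unless ``keep_all_runs`` is set, only one run survives: the run whose last
    fix is nearest the travel destination (the school in the morning, home in
    the afternoon) when ``anchors`` — participant_id -> (home, school) — are
    given, else the first run.
    """
    config = config or GpsConfig()
    windows = windows or DEFAULT_WINDOWS
    if points.empty:
        return []
    df = points.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["_date"] = df["timestamp"].dt.date
    df["_direction"] = df["timestamp"].dt.time.map(lambda t: window_of(t, windows))
    df = df[df["_direction"].notna()]
    trips: list[Trip] = []
    for (pid, date, direction), grp in df.groupby(
            ["participant_id", "_date", "_direction"], sort=True):
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        runs = _split_runs(grp, config.max_gap_s)
        if not config.keep_all_runs and len(runs) > 1:
            if anchors is not None and pid in anchors:
                home, school = anchors[pid]
                dest = school if direction == "to_school" else home
                dists = [float(np.hypot(r["x"].iloc[-1] - dest.x,
                                        r["y"].iloc[-1] - dest.y)) for r in runs]
                runs = [runs[int(np.argmin(dists))]]
            else:
                runs = [runs[0]]
        for run in runs:
            if len(run) >= config.min_trip_points:
                trips.append(Trip(pid, date, direction,
                                  run.drop(columns=["_date", "_direction"])))
    return trips


def classify_walking(trip: Trip, speed_max: float = 10.0) -> bool:
    """True iff the trip's mean speed is strictly below ``speed_max`` m/s.

    Mean speed is total consecutive-fix path length over elapsed time; a trip
    with zero elapsed time is never walking.
    """
    if trip.n_points < 2:
        raise DataError("walking classification needs at least two fixes")
    return trip.mean_speed < speed_max


# -- post-processing -------------------------------------------------------


def remove_outliers(trip: Trip, threshold: float = 100.0) -> Trip | None:
    """Drop fixes farther than ``threshold`` from every other fix; iterate to
    a fixed point.  Returns None (with the caller expected to log) when no
    fixes survive."""
    frame = trip.frame
    while True:
        n = len(frame)
        if n == 0:
            return None
        if n == 1:
            return None  # a single fix cannot form a trip line
        xy = frame[["x", "y"]].to_numpy(float)
        d = np.hypot(xy[:, None, 0] - xy[None, :, 0],
                     xy[:, None, 1] - xy[None, :, 1])
        np.fill_diagonal(d, np.inf)
        keep = d.min(axis=1) <= threshold
        if keep.all():
            return Trip(trip.participant_id, trip.date, trip.direction,
                        frame.reset_index(drop=True))
        frame = frame[keep]


def build_gps_route(trip: Trip, home: Point, school: Point) -> RouteRecord:
    """Polyline through the trip's fixes with anchors appended in travel order.

    ``to_school`` routes run home -> fixes -> school; ``home`` routes run
    school -> fixes -> home.
    """
    coords = list(zip(trip.frame["x"].to_numpy(float),
                      trip.frame["y"].to_numpy(float)))
    if trip.direction == "to_school":
        coords = [(home.x, home.y)] + coords + [(school.x, school.y)]
    else:
        coords = [(school.x, school.y)] + coords + [(home.x, home.y)]
    distinct = {(round(x, 9), round(y, 9)) for x, y in coords}
    if len(distinct) < 2:
        raise DataError("degenerate GPS route: fewer than two distinct vertices")
    return RouteRecord(participant_id=trip.participant_id,
                       direction=trip.direction, source=GPS,
                       geometry=LineString(coords))


# -- end-to-end extraction -------------------------------------------------


def extract_routes(points: pd.DataFrame,
                   participants: dict[str, Participant],
                   buildings: list[Polygon],
                   school_footprints: dict[str, Polygon],
                   schools: dict[str, Point],
                   config: GpsConfig | None = None,
                   windows: dict | None = None):
    """Run the full workflow; returns (routes, report, rejected).

    ``report`` holds the stage counts of the workflow diagram: raw points,
    points surviving the inclusion criteria, points in trips, trips, walking
    trips, trips after outlier removal, and final routes.
    """
    config = config or GpsConfig()
    kept, rejected = filter_points(points, participants, buildings,
                                   school_footprints, config, windows)
    anchors = {pid: (p.home, schools[p.school_id])
               for pid, p in participants.items() if p.school_id in schools}
    trips = segment_trips(kept, config, windows, anchors)
    walking = [t for t in trips if classify_walking(t, config.walking_speed_max)]
    cleaned = [t for t in (remove_outliers(t, config.outlier_threshold_m)
                           for t in walking) if t is not None]
    routes = []
    for t in cleaned:
        part = participants[t.participant_id]
        school_pt = schools[part.school_id]
        try:
            routes.append(build_gps_route(t, part.home, school_pt))
        except DataError:
            continue
    report = {
        "n_raw_points": int(len(points)),
        "n_points_after_inclusion": int(len(kept)),
        "n_points_in_trips": int(sum(t.n_points for t in trips)),
        "n_trips": len(trips),
        "n_walking_trips": len(walking),
        "n_trips_after_outliers": len(cleaned),
        "n_routes": len(routes),
        "rejections_by_criterion":
            rejected["criterion"].value_counts().to_dict() if len(rejected) else {},
    }
    return routes, report, rejected
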