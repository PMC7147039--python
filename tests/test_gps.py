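"""Inclusion filters, trip building, walking classification, outliers."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from commute_exposure import (
    GpsConfig, Participant, Trip, build_gps_route, classify_walking,
    filter_points, remove_outliers, segment_trips,
)
from commute_exposure.errors import DataError

HOME = Point(0.0, 0.0)
SCHOOL = Point(1000.0, 0.0)
PARTS = {"P0": Participant("P0", HOME, "S0")}
FOOTPRINTS = {"S0": box(985, -15, 1015, 15)}


def frame(rows):
    df = pd.DataFrame(rows, columns=["participant_id", "timestamp", "x", "y"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


MON = "2013-01-07"  # a Monday
SAT = "2013-01-12"


@pytest.mark.parametrize("ts,x,y,kept,criterion", [
    (f"{MON} 07:45", 50.0, 0.0, True, None),            # all criteria pass
    (f"{MON} 12:00", 500.0, 0.0, False, "commute_window"),
    (f"{MON} 08:00", 30.0, 0.0, False, "near_home"),    # 30 m from home
    (f"{SAT} 08:00", 500.0, 0.0, False, "weekday"),
    (f"{MON} 08:00", 1000.0, 0.0, False, "school_footprint"),
    (f"{MON} 15:00", 500.0, 200.0, False, "building_footprint"),
])
def test_inclusion_criteria(ts, x, y, kept, criterion):
    buildings = [box(480, 180, 520, 220)]
    pts = frame([("P0", ts, x, y)])
    keep, rej = filter_points(pts, PARTS, buildings, FOOTPRINTS)
    assert (len(keep) == 1) == kept
    if not kept:
        assert rej["criterion"].iloc[0] == criterion


def test_filter_boundary_40m_exclusive():
    # exactly 40 m is not "more than 40 m away" -> removed
    pts = frame([("P0", f"{MON} 08:00", 40.0, 0.0),
                 ("P0", f"{MON} 08:00", 40.001, 0.0)])
    keep, rej = filter_points(pts, PARTS, [], FOOTPRINTS)
    assert len(keep) == 1 and keep["x"].iloc[0] == pytest.approx(40.001)


def test_filter_unparseable_timestamp_logged():
    pts = pd.DataFrame([("P0", "not-a-date", 500.0, 0.0)],
                       columns=["participant_id", "timestamp", "x", "y"])
    keep, rej = filter_points(pts, PARTS, [], FOOTPRINTS)
    assert len(keep) == 0
    assert rej["criterion"].iloc[0] == "bad_timestamp"


def test_filter_idempotent(fixture_town, participants_of):
    town, cohort = fixture_town
    parts = participants_of(town)
    once, _ = filter_points(cohort.points_frame(), parts,
                            town.layers.buildings, town.school_footprints)
    twice, rej2 = filter_points(once, parts, town.layers.buildings,
                                town.school_footprints)
    assert len(rej2) == 0
    pd.testing.assert_frame_equal(
        once.reset_index(drop=True), twice.reset_index(drop=True))


def _morning_run(n, start="08:00", spacing_s=10, speed=1.4, date=MON):
    t0 = pd.Timestamp(f"{date} {start}")
    return [("P0", t0 + timedelta(seconds=i * spacing_s),
             100.0 + i * spacing_s * speed, 0.0) for i in range(n)]


def test_segmentation_basic():
    trips = segment_trips(frame(_morning_run(10)))
    assert len(trips) == 1
    assert trips[0].direction == "to_school"
    assert trips[0].n_points == 10


def test_segmentation_two_dates_two_trips():
    rows = _morning_run(5) + _morning_run(5, date="2013-01-08")
    trips = segment_trips(frame(rows))
    assert len(trips) == 2


def test_segmentation_single_fix_is_no_trip():
    trips = segment_trips(frame(_morning_run(1)))
    assert trips == []


def test_segmentation_order_invariance():
    rows = _morning_run(8) + _morning_run(6, start="15:00")
    df = frame(rows)
    shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a = segment_trips(df)
    b = segment_trips(shuffled)
    assert len(a) == len(b) == 2
    for ta, tb in zip(a, b):
        assert ta.direction == tb.direction
        pd.testing.assert_frame_equal(
            ta.frame.reset_index(drop=True), tb.frame.reset_index(drop=True))


def test_segmentation_keeps_run_nearest_destination():
    # two runs in one morning window separated by a large gap: the second
    # ends nearer the school and wins when anchors are known
    rows = _morning_run(5, start="07:35")
    t0 = pd.Timestamp(f"{MON} 08:40")
    rows += [("P0", t0 + timedelta(seconds=i * 10), 800.0 + i * 14, 0.0)
             for i in range(5)]
    trips = segment_trips(frame(rows), anchors={"P0": (HOME, SCHOOL)})
    assert len(trips) == 1
    assert trips[0].frame["x"].iloc[0] == pytest.approx(800.0)
    # keep_all_runs override retains both
    trips2 = segment_trips(frame(rows), GpsConfig(keep_all_runs=True))
    assert len(trips2) == 2


@pytest.mark.parametrize("speed,expect", [(1.4, True), (10.0, False),
                                          (12.0, False)])
def test_walking_speed_threshold_is_strict(speed, expect):
    rows = _morning_run(10, spacing_s=10, speed=speed)
    trip = segment_trips(frame(rows))[0]
    assert classify_walking(trip) is expect
    assert trip.mean_speed == pytest.approx(speed)


def test_outlier_removal_examples_and_oracle():
    # chain 20 m apart: unchanged
    rows = [("P0", pd.Timestamp(f"{MON} 08:00") + timedelta(seconds=i),
             20.0 * i, 0.0) for i in range(10)]
    trip = Trip("P0", MON, "to_school", frame(rows))
    assert remove_outliers(trip, 100).n_points == 10
    # one fix 150 m from all others: removed
    rows[5] = ("P0", rows[5][1], 100.0, 150.0)
    trip = Trip("P0", MON, "to_school", frame(rows))
    cleaned = remove_outliers(trip, 100)
    assert cleaned.n_points == 9
    assert not ((cleaned.frame["y"] == 150.0).any())


def test_outlier_removal_matches_bruteforce_fixed_point():
    rng = np.random.default_rng(4)
    for _ in range(10):
        n = int(rng.integers(5, 50))
        xy = rng.uniform(0, 400, size=(n, 2))
        rows = [("P0", pd.Timestamp(f"{MON} 08:00") + timedelta(seconds=i),
                 float(x), float(y)) for i, (x, y) in enumerate(xy)]
        trip = Trip("P0", MON, "to_school", frame(rows))
        got = remove_outliers(trip, 100)
        # independent O(n^2) fixed-point oracle
        pts = list(map(tuple, xy))
        while True:
            keep = []
            for i, p in enumerate(pts):
                dmin = min(np.hypot(p[0] - q[0], p[1] - q[1])
                           for j, q in enumerate(pts) if j != i)
                if dmin <= 100:
                    keep.append(p)
            if len(keep) == len(pts) or len(keep) < 2:
                pts = keep
                break
            pts = keep
        if len(pts) < 2:
            assert got is None
        else:
            assert got.n_points == len(pts)
            np.testing.assert_allclose(
                got.frame[["x", "y"]].to_numpy(), np.array(pts))


def test_outlier_threshold_monotone():
    rng = np.random.default_rng(5)
    xy = rng.uniform(0, 500, size=(30, 2))
    rows = [("P0", pd.Timestamp(f"{MON} 08:00") + timedelta(seconds=i),
             float(x), float(y)) for i, (x, y) in enumerate(xy)]
    trip = Trip("P0", MON, "to_school", frame(rows))
    kept = []
    for thr in (50, 100, 200, 400):
        out = remove_outliers(trip, thr)
        kept.append(0 if out is None else out.n_points)
    assert kept == sorted(kept)


def test_gps_route_endpoints_and_length():
    rows = _morning_run(3, spacing_s=100, speed=1.0)  # fixes 100 m apart
    trip = segment_trips(frame(rows))[0]
    route = build_gps_route(trip, HOME, SCHOOL)
    coords = list(route.geometry.coords)
    assert Point(coords[0]).distance(HOME) < 1e-9
    assert Point(coords[-1]).distance(SCHOOL) < 1e-9
    # additivity: home->100 + 2x100 + 300->school = 100+200+700
    assert route.length_km * 1000 == pytest.approx(1000.0)
    # afternoon mirror
    rows_pm = [("P0", pd.Timestamp(f"{MON} 15:00") + timedelta(seconds=i),
                x, y) for (_, _, x, y) in rows for i in [0]]
    rows_pm = [("P0", pd.Timestamp(f"{MON} 15:00") + timedelta(seconds=k * 100),
                r[2], r[3]) for k, r in enumerate(rows[::-1])]
    trip_pm = segment_trips(frame(rows_pm))[0]
    route_pm = build_gps_route(trip_pm, HOME, SCHOOL)
    assert list(route_pm.geometry.coords) == list(route.geometry.coords)[::-1]


def test_degenerate_route_rejected():
    rows = [("P0", pd.Timestamp(f"{MON} 08:00"), 0.0, 0.0),
            ("P0", pd.Timestamp(f"{MON} 08:01"), 0.0, 0.0)]
    trip = Trip("P0", MON, "to_school", frame(rows))
    with pytest.raises(DataError):
        build_gps_route(trip, Point(0, 0), Point(0, 0))
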