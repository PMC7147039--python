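"""Synthetic town and cohort generator."""

import json

import numpy as np
import pytest
from shapely.geometry import mapping

from commute_exposure import (
    CostTable, TownSpec, WalkerSpec, generate_cohort, generate_town,
    generate_walkers,
)
from commute_exposure.config import ROAD_CLASSES
from commute_exposure.errors import ConfigError


def serialize_town(town):
    return json.dumps({
        "arcs": [(a.arc_id, a.from_node, a.to_node, a.road_class,
                  mapping(a.geometry)["coordinates"]) for a in town.network.arcs],
        "lights": [mapping(p)["coordinates"] for p in town.layers.traffic_lights],
        "outlets": [mapping(p)["coordinates"] for p in town.layers.outlets],
        "pairs": [(p.participant_id, p.home.x, p.home.y, p.school_id)
                  for p in town.pairs],
    })


def test_seeded_determinism_bit_for_bit():
    spec = dict(grid_rows=5, grid_cols=5, n_homes=6, n_schools=2, seed=3)
    t1 = generate_town(TownSpec(**spec))
    t2 = generate_town(TownSpec(**spec))
    assert serialize_town(t1) == serialize_town(t2)
    c1 = generate_walkers(t1, t1.pairs, WalkerSpec(n_walkers=6, seed=4))
    c2 = generate_walkers(t2, t2.pairs, WalkerSpec(n_walkers=6, seed=4))
    assert c1.points_frame().to_csv() == c2.points_frame().to_csv()


def test_town_structure_and_connectivity():
    town = generate_town(TownSpec(grid_rows=6, grid_cols=7, seed=5,
                                  n_homes=8, n_schools=2))
    net = town.network
    assert net.is_connected()
    assert all(a.road_class in ROAD_CLASSES for a in net.arcs)
    # homes/schools on distinct nodes; every school serves >= 2 homes
    home_nodes = {p.home_node for p in town.pairs}
    school_nodes = {net.snap(s.point)[0] for s in town.schools.values()}
    assert home_nodes.isdisjoint(school_nodes)
    for sid in town.schools:
        assert sum(p.school_id == sid for p in town.pairs) >= 2
    # amenity points lie on or within 10 m of an arc
    for p in town.layers.outlets + town.layers.pedestrian_crossings:
        assert min(p.distance(a.geometry) for a in net.arcs) <= 10 + 1e-6


def test_zero_outlets_gives_empty_layer():
    town = generate_town(TownSpec(n_outlets=0, seed=6))
    assert town.layers.outlets == []


def test_class_mix_tracks_request_over_seeds():
    mix = {"main": 0.1, "residential": 0.6, "footpath": 0.2, "minor": 0.1}
    fracs = []
    for seed in range(20):
        town = generate_town(TownSpec(grid_rows=6, grid_cols=6,
                                      class_mix=mix, seed=seed))
        by_class = town.network.total_length_by_class()
        total = sum(by_class.values())
        fracs.append(by_class["residential"] / total)
    assert np.mean(fracs) == pytest.approx(0.6, abs=0.10)


def test_invalid_specs_rejected():
    with pytest.raises(ConfigError):
        TownSpec(class_mix={"main": 1.0}).validate()
    with pytest.raises(ConfigError):
        TownSpec(block_length=-5).validate()
    with pytest.raises(ConfigError):
        WalkerSpec(walk_speed=12.0).validate()
    with pytest.raises(ConfigError):
        WalkerSpec(gps_noise_sd=-1).validate()
    with pytest.raises(ConfigError):
        WalkerSpec(p_to_school=1.5).validate()


def noise_free_spec(**kw):
    return WalkerSpec(gps_noise_sd=0.0, preference_sd=0.0,
                      route_noise_sd=0.0, p_partial=0.0, decoy_fraction=0.0,
                      **kw)


def test_zero_noise_fixes_lie_on_true_path():
    town, cohort = generate_cohort(TownSpec(seed=7),
                                   noise_free_spec(n_walkers=8, seed=8))
    truth = cohort.true_routes
    for p in cohort.points:
        key = None
        for d in ("to_school", "home"):
            if (p.participant_id, d) in truth:
                geom = truth[(p.participant_id, d)].geometry
                from shapely.geometry import Point
                if geom.distance(Point(p.x, p.y)) < 1e-6:
                    key = (p.participant_id, d)
                    break
        assert key is not None, f"fix off every true path: {p}"


def test_uniform_costs_walk_the_distance_shortest_path():
    town, cohort = generate_cohort(
        TownSpec(seed=9),
        noise_free_spec(n_walkers=8, seed=10,
                        ground_truth_costs=CostTable.uniform()))
    for (pid, d), tr in cohort.true_routes.items():
        pair = next(p for p in town.pairs if p.participant_id == pid)
        o, dd = ((pair.home_node, pair.school_node) if d == "to_school"
                 else (pair.school_node, pair.home_node))
        _, w = town.network.shortest_path_nodes(o, dd, "distance")
        assert tr.geometry.length == pytest.approx(w, rel=1e-9)


def test_gps_noise_rms_close_to_nominal():
    sd = 5.0
    town, cohort = generate_cohort(
        TownSpec(grid_rows=8, grid_cols=8, seed=11),
        WalkerSpec(n_walkers=25, gps_noise_sd=sd, preference_sd=0.0,
                   route_noise_sd=0.0, p_partial=0.0, decoy_fraction=0.0,
                   seed=12))
    from shapely.geometry import Point
    disp = []
    for p in cohort.points:
        for d in ("to_school", "home"):
            key = (p.participant_id, d)
            if key in cohort.true_routes:
                disp.append(cohort.true_routes[key].geometry.distance(
                    Point(p.x, p.y)))
                break
    disp = np.array(disp)
    assert len(disp) >= 1000
    rms = np.sqrt((disp ** 2).mean())
    assert rms == pytest.approx(sd, rel=0.15)


def test_timestamps_weekdays_inside_windows():
    town, cohort = generate_cohort(TownSpec(seed=13),
                                   noise_free_spec(n_walkers=10, seed=14))
    for p in cohort.points:
        assert p.timestamp.weekday() < 5
        t = p.timestamp.time()
        assert (t >= p.timestamp.replace(hour=7, minute=30).time()
                and t <= p.timestamp.replace(hour=9, minute=30).time()) or \
               (t >= p.timestamp.replace(hour=14, minute=30).time()
                and t <= p.timestamp.replace(hour=16, minute=30).time())


def test_decoy_fraction_and_labels():
    town, cohort = generate_cohort(
        TownSpec(seed=15),
        WalkerSpec(n_walkers=10, gps_noise_sd=0.0, decoy_fraction=0.1,
                   seed=16))
    labels = {p.label for p in cohort.points}
    assert "commute" in labels
    assert labels & {"decoy_midday", "decoy_building", "decoy_home",
                     "decoy_weekend"}
    n_commute = sum(p.label == "commute" for p in cohort.points)
    n_decoy = sum(p.label != "commute" for p in cohort.points)
    assert n_decoy == pytest.approx(0.1 * n_commute, rel=0.2)
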