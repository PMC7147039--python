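"""File formats: GeoJSON for geometry, CSV for tables, YAML for configs.

Coordinates are planar meters throughout (no geographic CRS); the GeoJSON
written here is the plain FeatureCollection structure with coordinates in
the study's metric system.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path

import pandas as pd
from shapely.geometry import Point, mapping, shape

from .errors import DataError
from .features import AmenityLayers
from .gps import Participant
from .network import HomeSchoolPair, RoadArc, RoadNetwork
from .routes import RouteRecord


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def _write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, separators=(",", ":"))


# -- road network ----------------------------------------------------------


def write_network_geojson(network: RoadNetwork, path: str | Path) -> None:
    feats = []
    for arc in network.arcs:
        feats.append({
            "type": "Feature",
            "geometry": mapping(arc.geometry),
            "properties": {"arc_id": arc.arc_id, "road_class": arc.road_class,
                           "from_node": arc.from_node, "to_node": arc.to_node},
        })
    _write_json(_feature_collection(feats), path)


def read_network_geojson(path: str | Path) -> RoadNetwork:
    """Read a classed LineString network.

    When from_node/to_node properties are absent (foreign files), node ids
    are derived by matching arc endpoints at 1e-6 m resolution.
    """
    with open(path) as fh:
        data = json.load(fh)
    arcs = []
    nodes: dict[int, tuple[float, float]] = {}
    coord_ids: dict[tuple[float, float], int] = {}

    def node_for(xy) -> int:
        key = (round(xy[0], 6), round(xy[1], 6))
        if key not in coord_ids:
            coord_ids[key] = len(coord_ids)
        return coord_ids[key]

    have_ids = all("from_node" in f.get("properties", {})
                   for f in data["features"])
    for k, feat in enumerate(data["features"]):
        geom = shape(feat["geometry"])
        props = feat.get("properties", {})
        if "road_class" not in props:
            raise DataError(f"feature {k} lacks a road_class property")
        coords = list(geom.coords)
        if have_ids:
            u, v = int(props["from_node"]), int(props["to_node"])
        else:
            u, v = node_for(coords[0]), node_for(coords[-1])
        nodes[u] = tuple(coords[0])
        nodes[v] = tuple(coords[-1])
        arcs.append(RoadArc(int(props.get("arc_id", k)), u, v, geom,
                            props["road_class"]))
    return RoadNetwork(nodes, arcs)


# -- amenity layers --------------------------------------------------------

_LAYER_FILES = {"traffic_lights": "traffic_lights.geojson",
                "outlets": "outlets.geojson",
                "accidents": "accidents.geojson",
                "pedestrian_crossings": "crossings.geojson",
                "bluespace": "bluespace.geojson",
                "woodland": "woodland.geojson",
                "buildings": "buildings.geojson"}


def write_layers(layers: AmenityLayers, out_dir: str | Path) -> None:
    out = Path(out_dir)
    for attr, fname in _LAYER_FILES.items():
        items = getattr(layers, attr)
        feats = []
        for item in items:
            if attr == "accidents":
                geom, ts = item
                props = {"timestamp": ts.isoformat()}
            else:
                geom, props = item, {}
            feats.append({"type": "Feature", "geometry": mapping(geom),
                          "properties": props})
        _write_json(_feature_collection(feats), out / fname)


def read_layers(layers_dir: str | Path) -> AmenityLayers:
    layers = AmenityLayers()
    for attr, fname in _LAYER_FILES.items():
        path = Path(layers_dir) / fname
        if not path.exists():
            continue
        with open(path) as fh:
            data = json.load(fh)
        items = []
        for feat in data["features"]:
            geom = shape(feat["geometry"])
            if attr == "accidents":
                ts = datetime.fromisoformat(feat["properties"]["timestamp"])
                items.append((geom, ts))
            else:
                items.append(geom)
        setattr(layers, attr, items)
    return layers


# -- routes ----------------------------------------------------------------


def write_routes_geojson(routes: list[RouteRecord], path: str | Path) -> None:
    feats = []
    for r in routes:
        feats.append({
            "type": "Feature",
            "geometry": mapping(r.geometry),
            "properties": {"participant_id": r.participant_id,
                           "direction": r.direction, "source": r.source,
                           "length_km": r.length_km},
        })
    _write_json(_feature_collection(feats), path)


def read_routes_geojson(path: str | Path) -> list[RouteRecord]:
    with open(path) as fh:
        data = json.load(fh)
    out = []
    for feat in data["features"]:
        p = feat["properties"]
        out.append(RouteRecord(participant_id=p["participant_id"],
                               direction=p["direction"], source=p["source"],
                               geometry=shape(feat["geometry"])))
    return out


# -- GPS and participant tables -------------------------------------------


def write_gps_csv(points_frame: pd.DataFrame, path: str | Path) -> None:
    df = points_frame.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_gps_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_participants_csv(pairs: list[HomeSchoolPair], path: str | Path) -> None:
    rows = [{"participant_id": p.participant_id, "home_x": p.home.x,
             "home_y": p.home.y, "school_id": p.school_id,
             "school_x": p.school.x, "school_y": p.school.y} for p in pairs]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_participants_csv(path: str | Path
                          ) -> tuple[dict[str, Participant], list[HomeSchoolPair],
                                     dict[str, Point]]:
    df = pd.read_csv(path)
    participants, pairs, schools = {}, [], {}
    for _, r in df.iterrows():
        pid = str(r["participant_id"])
        home = Point(float(r["home_x"]), float(r["home_y"]))
        school = Point(float(r["school_x"]), float(r["school_y"]))
        sid = str(r["school_id"])
        participants[pid] = Participant(pid, home, sid)
        pairs.append(HomeSchoolPair(pid, home, sid, school))
        schools[sid] = school
    return participants, pairs, schools


def write_school_footprints(footprints: dict, path: str | Path) -> None:
    feats = [{"type": "Feature", "geometry": mapping(poly),
              "properties": {"school_id": sid}}
             for sid, poly in footprints.items()]
    _write_json(_feature_collection(feats), path)


def read_school_footprints(path: str | Path) -> dict:
    with open(path) as fh:
        data = json.load(fh)
    return {f["properties"]["school_id"]: shape(f["geometry"])
            for f in data["features"]}
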