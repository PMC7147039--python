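"""End-to-end orchestration of the four-step method.

(i) process GPS points into walking commute routes and generate the
shortest network routes; (ii) compute built-environment characteristics and
fit the route-choice model; (iii) turn odds ratios into impedance costs and
generate weighted network routes and exposures; (iv) validate with the 50 m
intersection metric and the school-clustered exposure regression.

`run_stages` is the in-memory core; `run_pipeline` wraps it with file I/O
from a RunConfig; `run_synthetic_study` wraps it around the synthetic
generator.  All randomness fans out from one global seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path


import pandas as pd

from . import io as ce_io
from .choice import RouteChoiceModel, build_pairs
from .config import DIRECTIONS, RunConfig
from .errors import CommuteExposureError, DataError
from .features import FeatureExtractor
from .gps import Participant, extract_routes
from .network import generate_snr
from .routes import GPS
from .validation import ExposureAgreementModel, overlap_summary, score_routes
from .weighting import (CostTable, SearchSpec, flag_arcs, generate_wnr,
                        optimize_costs)

#: default covariate set for fully on-network synthetic studies: the
#: compact set that stays estimable when routes are fully classified (the
#: four class percentages are collinear within pairs, and length/bluespace/
#: footpath push the near-optimising cohort into quasi-separation; see
#: docs/methods.md).  Real-data entry points use DEFAULT_COVARIATES.
STUDY_COVARIATES = ("n_traffic_lights", "n_outlets", "pct_residential",
                    "pct_main")

_OR_SLOTS = {"pct_main": "main", "pct_residential": "residential",
             "pct_footpath": "footpath", "pct_minor": "minor",
             "n_traffic_lights": "traffic_light", "n_outlets": "outlet"}


def ors_to_slots(fit_result) -> dict[str, float]:
    """Map fitted covariate odds ratios onto cost-table slot names."""
    ors = fit_result.odds_ratios
    return {slot: float(ors[cov]) for cov, slot in _OR_SLOTS.items()
            if cov in ors.index}


@dataclass
class StudyResult:
    """Everything the pipeline produced, stage by stage."""

    gps_routes: list = field(default_factory=list)
    snr_routes: list = field(default_factory=list)
    wnr_routes: list = field(default_factory=list)
    feature_frame: pd.DataFrame | None = None
    choice_fits: dict = field(default_factory=dict)      # direction -> results
    cost_tables: dict = field(default_factory=dict)      # direction -> CostTable
    search_traces: dict = field(default_factory=dict)
    intersections: pd.DataFrame | None = None
    overlap: pd.DataFrame | None = None
    exposure_fits: dict = field(default_factory=dict)    # direction -> results
    report: dict = field(default_factory=dict)

    def report_json(self) -> str:
        return json.dumps(self.report, indent=2, default=str)


def run_stages(network, layers, pairs, participants, schools,
               school_footprints, points: pd.DataFrame,
               config: RunConfig | None = None,
               covariates: tuple = STUDY_COVARIATES,
               stepwise: bool = True,
               fit_method: str = "firth") -> StudyResult:
    """Run the full method on in-memory inputs."""
    config = config or RunConfig()
    config.validate()
    res = StudyResult()
    report: dict = {"seed": config.seed}

    # -- step i: GPS processing and shortest network routes ---------------
    gps_routes, gps_report, rejected = extract_routes(
        points, participants, layers.buildings, school_footprints, schools,
        config.gps_config)
    if not gps_routes:
        raise DataError("GPS processing yielded no routes")
    res.gps_routes = gps_routes
    report["gps"] = gps_report

    with_gps = {r.participant_id for r in gps_routes}
    route_pairs = [p for p in pairs if p.participant_id in with_gps]
    res.snr_routes = generate_snr(network, route_pairs,
                                  snap_max=config.snap_max_distance)
    report["n_snr_routes"] = len(res.snr_routes)

    # -- step ii: characteristics and route-choice model ------------------
    flag_arcs(network, layers, buffer=config.flag_buffer)
    extractor = FeatureExtractor(network, layers, config.feature_config)
    res.feature_frame = extractor.feature_frame(res.gps_routes + res.snr_routes)
    report["choice_model"] = {}
    pair_log: dict[str, list[str]] = {}
    for direction in DIRECTIONS:
        matched, skipped = build_pairs(res.feature_frame, direction)
        pair_log[direction] = skipped
        if len(matched) < 10:
            warnings.warn(f"too few matched pairs for direction {direction}; "
                          "skipping the choice model")
            continue
        model = RouteChoiceModel.from_pairs(matched, covariates)
        fit = (model.fit_stepwise(alpha=config.stepwise_alpha,
                                  method=fit_method) if stepwise
               else model.fit(method=fit_method))
        res.choice_fits[direction] = fit
        report["choice_model"][direction] = fit.to_dict()
        report["choice_model"][direction]["n_pairs_skipped"] = len(skipped)

    # -- step iii: weighted network routes --------------------------------
    for direction in DIRECTIONS:
        table, trace = _resolve_cost_table(network, route_pairs, res, direction,
                                           config)
        res.cost_tables[direction] = table
        if trace is not None:
            res.search_traces[direction] = trace
        res.wnr_routes.extend(
            generate_wnr(network, route_pairs, table,
                         snap_max=config.snap_max_distance))
    report["cost_tables"] = {d: t.slot_values()
                             for d, t in res.cost_tables.items()}
    report["n_wnr_routes"] = len(res.wnr_routes)

    # -- step iv: validation ----------------------------------------------
    res.intersections = score_routes(res.snr_routes + res.wnr_routes,
                                     res.gps_routes,
                                     buffer=config.intersection_buffer)
    res.overlap = overlap_summary(res.intersections)
    report["overlap"] = res.overlap.to_dict("records")

    exposure = _exposure_table(res, layers, pairs)
    report["exposure_model"] = {}
    for direction in DIRECTIONS:
        sub = exposure[exposure["direction"] == direction]
        if len(sub) < 10:
            continue
        fit = ExposureAgreementModel(sub["gps_exposure"], sub["wne"],
                                     sub["school_id"]).fit()
        res.exposure_fits[direction] = fit
        report["exposure_model"][direction] = fit.to_dict()

    report["consistency"] = {
        "pair_log": pair_log,
        "counts_non_increasing": _counts_non_increasing(gps_report),
    }
    res.report = report
    return res


def _resolve_cost_table(network, route_pairs, res: StudyResult, direction: str,
                        config: RunConfig):
    """Fixed table > explicit grids > grids seeded from the fitted ORs."""
    if config.cost_tables and direction in config.cost_tables:
        return CostTable.from_slots(config.cost_tables[direction], direction), None
    if config.cost_grids and direction in config.cost_grids:
        spec = SearchSpec(grids=config.cost_grids[direction],
                          direction=direction, seed=config.seed)
    elif direction in res.choice_fits:
        spec = SearchSpec.seeded_from_ors(ors_to_slots(res.choice_fits[direction]),
                                          direction, seed=config.seed)
    else:
        return CostTable.uniform(direction=direction), None
    table, trace = optimize_costs(
        network, route_pairs, res.gps_routes, spec,
        intersection_buffer=config.intersection_buffer,
        snap_max=config.snap_max_distance)
    return table, trace


def _exposure_table(res: StudyResult, layers, pairs) -> pd.DataFrame:
    """Per participant-direction: GPS outlet exposure vs WNE, with school id."""
    school_of = {p.participant_id: p.school_id for p in pairs}
    ff = res.feature_frame
    gps = ff[ff["source"] == GPS].groupby(["participant_id", "direction"])[
        "n_outlets"].mean()
    rows = []
    for wnr in res.wnr_routes:
        key = (wnr.participant_id, wnr.direction)
        if key not in gps.index:
            continue
        from .weighting import compute_wne
        rows.append({"participant_id": wnr.participant_id,
                     "direction": wnr.direction,
                     "gps_exposure": float(gps[key]),
                     "wne": compute_wne(wnr, layers.outlets),
                     "school_id": school_of.get(wnr.participant_id, "?")})
    return pd.DataFrame(rows)


def _counts_non_increasing(gps_report: dict) -> bool:
    seq = [gps_report["n_raw_points"], gps_report["n_points_after_inclusion"],
           gps_report["n_points_in_trips"]]
    return all(a >= b for a, b in zip(seq, seq[1:]))


# -- wrappers --------------------------------------------------------------


def run_synthetic_study(town_spec=None, walker_spec=None,
                        config: RunConfig | None = None,
                        covariates: tuple = STUDY_COVARIATES,
                        stepwise: bool = True,
                        fit_method: str = "firth"):
    """Generate a synthetic town + cohort and run the full method on it.

    Returns (town, cohort, StudyResult).
    """
    from .synth import TownSpec, WalkerSpec, generate_cohort

    config = config or RunConfig()
    town_spec = town_spec or TownSpec(seed=config.seed)
    walker_spec = walker_spec or WalkerSpec(seed=config.seed + 1)
    town, cohort = generate_cohort(town_spec, walker_spec)
    participants = {p.participant_id: Participant(p.participant_id, p.home,
                                                  p.school_id)
                    for p in town.pairs}
    result = run_stages(town.network, town.layers, town.pairs, participants,
                        town.school_points, town.school_footprints,
                        cohort.points_frame(), config, covariates, stepwise,
                        fit_method)
    return town, cohort, result


def run_pipeline(config: RunConfig) -> StudyResult:
    """File-based run: read every input from config paths, write all outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load inputs"
    try:
        network = ce_io.read_network_geojson(config.network)
        layers = ce_io.read_layers(config.layers_dir)
        participants, pairs, schools = ce_io.read_participants_csv(config.homes)
        school_footprints = ce_io.read_school_footprints(config.schools)
        points = ce_io.read_gps_csv(config.gps)
        stage = "run stages"
        res = run_stages(network, layers, pairs, participants, schools,
                         school_footprints, points, config)
        stage = "write outputs"
        ce_io.write_routes_geojson(res.gps_routes, out / "gps_routes.geojson")
        ce_io.write_routes_geojson(res.snr_routes, out / "snr_routes.geojson")
        ce_io.write_routes_geojson(res.wnr_routes, out / "wnr_routes.geojson")
        res.feature_frame.to_csv(out / "route_features.csv", index=False)
        res.intersections.to_csv(out / "intersections.csv", index=False)
        res.overlap.to_csv(out / "overlap_summary.csv", index=False)
        from .weighting import cost_tables_to_yaml
        cost_tables_to_yaml(res.cost_tables, out / "cost_tables.yaml")
        with open(out / "report.json", "w") as fh:
            fh.write(res.report_json())
    except CommuteExposureError as err:
        raise type(err)(f"pipeline failed at stage '{stage}': {err}") from err
    return res


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict:
    """Write a small deterministic fixture set (town + cohort files).

    Used by the test suite and the CLI examples; regeneration with the same
    seed is byte-identical.
    """
    from .synth import TownSpec, WalkerSpec, generate_cohort
    from .weighting import DEFAULT_COST_TABLES

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    town_spec = TownSpec(grid_rows=6, grid_cols=6, n_homes=12, n_schools=2,
                         n_outlets=10, n_traffic_lights=8, seed=seed)
    walker_spec = WalkerSpec(n_walkers=12, gps_noise_sd=3.0, seed=seed + 1)
    town, cohort = generate_cohort(town_spec, walker_spec)
    ce_io.write_network_geojson(town.network, out / "network.geojson")
    ce_io.write_layers(town.layers, out / "layers")
    ce_io.write_participants_csv(town.pairs, out / "participants.csv")
    ce_io.write_school_footprints(town.school_footprints,
                                  out / "schools.geojson")
    ce_io.write_gps_csv(cohort.points_frame(), out / "gps.csv")
    cfg = RunConfig(network=str(out / "network.geojson"),
                    gps=str(out / "gps.csv"),
                    homes=str(out / "participants.csv"),
                    schools=str(out / "schools.geojson"),
                    layers_dir=str(out / "layers"),
                    out_dir=str(out / "results"),
                    cost_tables={d: t.slot_values()
                                 for d, t in DEFAULT_COST_TABLES.items()},
                    seed=seed)
    cfg.to_yaml(out / "config.yaml")
    return {"out_dir": str(out), "n_points": len(cohort.points),
            "n_pairs": len(town.pairs)}
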