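import warnings

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from commute_exposure import (
    GpsConfig, HomeSchoolPair, Participant, RoadArc, RoadNetwork, TownSpec,
    WalkerSpec, generate_cohort,
)
from commute_exposure.weighting import CostTable

warnings.filterwarnings("ignore", category=UserWarning)


def make_random_graph(seed: int, n_nodes: int = 8) -> RoadNetwork:
    """Small connected random network with random positive weights."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_nodes + 1))
    pos = {i: (float(rng.uniform(0, 1000)), float(rng.uniform(0, 1000)))
           for i in range(n)}
    edges = set()
    order = list(rng.permutation(n))
    for a, b in zip(order[:-1], order[1:]):   # random spanning tree
        edges.add((min(a, b), max(a, b)))
    extra = int(rng.integers(1, n))
    for _ in range(extra):
        a, b = rng.choice(n, 2, replace=False)
        edges.add((min(int(a), int(b)), max(int(a), int(b))))
    classes = ("main", "residential", "footpath", "minor")
    arcs = []
    for k, (u, v) in enumerate(sorted(edges)):
        arc = RoadArc(k, u, v, LineString([pos[u], pos[v]]),
                      classes[k % 4])
        arc.cost_per_m = float(rng.uniform(0.2, 3.0))
        arcs.append(arc)
    return RoadNetwork(pos, arcs)


@pytest.fixture(scope="session")
def fixture_town():
    """Small deterministic town + cohort with mild GPS noise."""
    town, cohort = generate_cohort(
        TownSpec(grid_rows=6, grid_cols=6, block_length=150.0, n_homes=12,
                 n_schools=2, n_outlets=10, n_traffic_lights=8, seed=11),
        WalkerSpec(n_walkers=12, gps_noise_sd=3.0, seed=12))
    return town, cohort


@pytest.fixture(scope="session")
def participants_of():
    def _make(town):
        return {p.participant_id: Participant(p.participant_id, p.home,
                                              p.school_id)
                for p in town.pairs}
    return _make


@pytest.fixture(scope="session")
def recovery_ground_truth():
    """Cost table favouring traffic lights and residential arcs, repelling
    food outlets (the direction pattern of the published models)."""
    return CostTable.from_slots(
        {"main": 1.0, "residential": 0.5, "footpath": 1.0, "minor": 1.5,
         "traffic_light": 0.4, "outlet": 2.5}, "to_school")
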