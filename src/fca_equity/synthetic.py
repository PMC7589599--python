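"""Synthetic demand/facility landscapes for testing and demonstration.

The generator emulates the structure of an island-wide study system: ~19
counties holding ~350 towns whose population-weighted centroids cluster
around a handful of urban cores, ~658 facilities totalling ~1,140 providers
that concentrate where population density is high, Google-style ratings
with mean ≈ 3.72 and SD ≈ 0.66 clipped to [1, 5], and route distances that
exceed straight-line distances.  These defaults are calibration targets for
the published national aggregates of the system emulated, not reproductions
of its unreleased town-level data.

Randomness comes exclusively from ``numpy.random.default_rng`` (PCG64), so
a fixed seed gives identical landscapes on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .core import DemandPoint, Facility, TravelCosts

__all__ = [
    "LandscapeConfig",
    "generate_landscape",
    "worked_example_fixture",
    "extended_example_fixture",
    "EXTENDED_EXPECTED",
]


@dataclass(frozen=True)
class LandscapeConfig:
    """Knobs of the synthetic landscape.

    ``population_lognormal`` are (μ, σ) of the per-town 65+ head count;
    the defaults give ≈10,400 elderly per town, ≈3.6M nationally.
    ``facility_intensity_exponent`` γ controls how strongly facilities
    track population density (0 = placement independent of population).
    ``capacity_mean`` is mean providers per facility (capacities are
    1 + Poisson(capacity_mean − 1), hence integers ≥ 1).  Route distances
    are Euclidean × ``detour_factor`` in the default "detour" model; the
    "network" model routes through a random geometric graph instead.
    """

    n_counties: int = 19
    towns_per_county: tuple[int, int] = (10, 27)
    n_urban_centers: int = 6
    population_lognormal: tuple[float, float] = (8.75, 1.0)
    facility_intensity_exponent: float = 1.5
    n_facilities: int = 658
    capacity_mean: float = 1.73
    rating_mean: float = 3.72
    rating_sd: float = 0.66
    rating_clip: tuple[float, float] = (1.0, 5.0)
    detour_factor: float = 1.3
    distance_model: str = "detour"  # "detour" | "network"
    store_within_km: float = 60.0
    extent_km: tuple[float, float] = (150.0, 350.0)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_counties < 1 or self.n_urban_centers < 1 or self.n_facilities < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.towns_per_county
        if lo < 1 or hi < lo:
            raise ValueError("towns_per_county must be a positive (lo, hi) range")
        if self.detour_factor < 1.0:
            raise ValueError("detour_factor must be >= 1")
        clo, chi = self.rating_clip
        if not (1.0 <= clo < chi <= 5.0):
            raise ValueError("rating_clip bounds must lie within [1, 5]")
        if self.capacity_mean < 1.0:
            raise ValueError("capacity_mean must be >= 1 provider per facility")
        if self.distance_model not in ("detour", "network"):
            raise ValueError("distance_model must be 'detour' or 'network'")


def generate_landscape(
    config: LandscapeConfig = LandscapeConfig(),
) -> tuple[list[DemandPoint], list[Facility], TravelCosts]:
    """Draw one landscape: towns, facilities, and sparse route distances.

    Counties are seeded around Gaussian urban clusters and towns around
    their county seat; town populations are log-normal.  Each facility
    picks a host town with probability ∝ (kernel population density)^γ and
    is jittered around it, so resources cluster in metros when γ > 0.
    Pairs farther than ``store_within_km`` are left out of the distance
    table (unreachable), keeping it sparse.
    """
    cfg = config
    rng = np.random.default_rng(cfg.random_seed)
    w, h = cfg.extent_km

    centers = np.column_stack(
        [rng.uniform(0.15 * w, 0.85 * w, cfg.n_urban_centers),
         rng.uniform(0.1 * h, 0.9 * h, cfg.n_urban_centers)]
    )
    county_cluster = rng.integers(0, cfg.n_urban_centers, cfg.n_counties)
    county_xy = centers[county_cluster] + rng.normal(0.0, 40.0, (cfg.n_counties, 2))
    county_xy = np.clip(county_xy, [0, 0], [w, h])

    lo, hi = cfg.towns_per_county
    towns_per = rng.integers(lo, hi + 1, cfg.n_counties)
    mu, sigma = cfg.population_lognormal

    demand: list[DemandPoint] = []
    xy_list = []
    for c in range(cfg.n_counties):
        cid = f"C{c + 1:02d}"
        for t in range(towns_per[c]):
            tid = f"{cid}T{t + 1:02d}"
            x, y = county_xy[c] + rng.normal(0.0, 12.0, 2)
            x, y = float(np.clip(x, 0, w)), float(np.clip(y, 0, h))
            pop = int(rng.lognormal(mu, sigma))
            demand.append(DemandPoint(tid, tid, cid, pop, x, y))
            xy_list.append((x, y))
    town_xy = np.asarray(xy_list)
    pops = np.array([d.population for d in demand], dtype=float)

    # kernel population density at each town (10-km Gaussian window)
    d2 = ((town_xy[:, None, :] - town_xy[None, :, :]) ** 2).sum(axis=2)
    dens = (pops[None, :] * np.exp(-d2 / (2 * 10.0**2))).sum(axis=1)
    gamma = cfg.facility_intensity_exponent
    weights = dens**gamma if gamma != 0 else np.ones_like(dens)
    weights = weights / weights.sum()

    host = rng.choice(len(demand), size=cfg.n_facilities, p=weights)
    caps = 1 + rng.poisson(cfg.capacity_mean - 1.0, cfg.n_facilities)
    ratings = np.clip(
        rng.normal(cfg.rating_mean, cfg.rating_sd, cfg.n_facilities),
        *cfg.rating_clip,
    )
    facilities: list[Facility] = []
    for k in range(cfg.n_facilities):
        tdp = demand[host[k]]
        fx, fy = np.array([tdp.x, tdp.y]) + rng.normal(0.0, 3.0, 2)
        facilities.append(
            Facility(
                id=f"F{k + 1:03d}",
                region_id=tdp.region_id,
                county_id=tdp.county_id,
                capacity=float(caps[k]),
                rating=float(np.round(ratings[k], 2)),
                x=float(np.clip(fx, 0, w)),
                y=float(np.clip(fy, 0, h)),
            )
        )

    if cfg.distance_model == "network":
        costs = _network_distances(demand, facilities, cfg, rng)
    else:
        costs = _detour_distances(demand, facilities, cfg)
    return demand, facilities, costs


def _detour_distances(demand, facilities, cfg) -> TravelCosts:
    """Route distance = Euclidean × detour factor, stored sparsely."""
    dxy = np.array([[d.x, d.y] for d in demand])
    fxy = np.array([[f.x, f.y] for f in facilities])
    eu = np.sqrt(((dxy[:, None, :] - fxy[None, :, :]) ** 2).sum(axis=2))
    route = eu * cfg.detour_factor
    costs = TravelCosts()
    keep = route <= cfg.store_within_km
    for r, c in zip(*np.nonzero(keep)):
        costs.set(demand[r].id, facilities[c].id, float(route[r, c]))
    return costs


def _network_distances(demand, facilities, cfg, rng) -> TravelCosts:
    """Shortest paths on a random geometric road graph over all sites.

    Sites within 20 km are linked by a road of length Euclidean × a
    lognormal wiggle ≥ 1; route distance is the graph shortest path.
    Disconnected pairs stay unreachable.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra
    from scipy.spatial import cKDTree

    xy = np.array(
        [[d.x, d.y] for d in demand] + [[f.x, f.y] for f in facilities]
    )
    n = len(xy)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(20.0, output_type="ndarray")
    if len(pairs) == 0:
        return TravelCosts()
    eu = np.sqrt(((xy[pairs[:, 0]] - xy[pairs[:, 1]]) ** 2).sum(axis=1))
    wiggle = 1.0 + rng.lognormal(-1.8, 0.6, len(pairs))
    lengths = eu * wiggle
    g = coo_matrix(
        (np.concatenate([lengths, lengths]),
         (np.concatenate([pairs[:, 0], pairs[:, 1]]),
          np.concatenate([pairs[:, 1], pairs[:, 0]]))),
        shape=(n, n),
    ).tocsr()
    nd = len(demand)
    dist = dijkstra(g, directed=False, indices=np.arange(nd),
                    limit=cfg.store_within_km)
    costs = TravelCosts()
    sub = dist[:, nd:]
    for r, c in zip(*np.nonzero(np.isfinite(sub))):
        costs.set(demand[r].id, facilities[c].id, float(sub[r, c]))
    return costs


# ---------------------------------------------------------------------------
# deterministic worked examples

def worked_example_fixture() -> tuple[list[DemandPoint], list[Facility], TravelCosts]:
    """Two towns sharing one facility: the hand-checkable 2SFCA instance.

    P = 1000 at 2 km and P = 3000 at 6 km from a facility with S = 2.
    Step 1: R = 2 / (1000·1 + 3000·0.5) = 8·10⁻⁴; step 2 gives A1 scores
    (8.0, 4.0) per 10,000, and Σ P·A/10,000 = 2 = S.
    """
    demand = [
        DemandPoint("i1", "i1", "C1", 1000, 0.0, 0.0),
        DemandPoint("i2", "i2", "C1", 3000, 6.0, 0.0),
    ]
    facilities = [Facility("j1", "i1", "C1", 2.0, 4.0, 0.0, 2.0)]
    costs = TravelCosts({("i1", "j1"): 2.0, ("i2", "j1"): 6.0})
    return demand, facilities, costs


#: A1-A4 scores of the extended fixture, frozen from an independent
#: per-definition double-loop computation.
EXTENDED_EXPECTED: dict[str, dict[str, float]] = {
    "A1": {"i1": 33.25581395348837, "i2": 10.764119601328906,
           "i3": 10.431893687707642},
    "A2": {"i1": 37.52328132654643, "i2": 7.138441358251951,
           "i3": 16.399671913899333},
    "A3": {"i1": 40.15107682189354, "i2": 6.543970970433368,
           "i3": 13.521962474479434},
    "A4": {"i1": 38.29449600450005, "i2": 6.930616496200432,
           "i3": 15.688542006198176},
}


def extended_example_fixture() -> tuple[list[DemandPoint], list[Facility], TravelCosts]:
    """Three towns and three facilities exercising every method feature.

    Includes an unreachable pair (i1-j3 beyond 30 km), a missing entry
    (i3-j1), unequal capacities and ratings, and all three decay bands.
    Shipped alongside the package as CSV data files; expected A1-A4
    scores (``EXTENDED_EXPECTED``) were frozen from an independent
    double-loop computation.
    """
    from . import io as _io

    base = resources.files("fca_equity").joinpath("data")
    demand = _io.read_demand(base.joinpath("example_demand.csv"))
    facilities = _io.read_facilities(base.joinpath("example_facilities.csv"))
    costs = _io.read_distances(base.joinpath("example_distances.csv"))
    return demand, facilities, costs
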