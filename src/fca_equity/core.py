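"""Domain types and the distance-decay kernel shared by every scoring method.

The accessibility methods consume three tables: demand points (population-
weighted town centroids carrying the 65+ population), facilities (service
points carrying provider capacity and a public 1-5 rating), and a sparse
demand-to-facility travel-distance matrix in km.  Distances are *inputs* —
route distances precomputed on a road network — never derived from the
coordinates, which exist only for simulation and GeoJSON export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "DemandPoint",
    "Facility",
    "TravelCosts",
    "DecayParams",
    "DEFAULT_DECAY",
    "distance_decay",
    "catchment",
]


@dataclass(frozen=True)
class DemandPoint:
    """A population-weighted town centroid with its elderly population.

    ``population`` is the head count of residents aged 65 and over; the
    region is the town itself, nested in a county used for equity reporting.
    Coordinates are planar (projected), in km.
    """

    id: str
    region_id: str
    county_id: str
    population: int
    x: float = 0.0
    y: float = 0.0

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError(f"demand point {self.id!r}: population must be >= 0")


@dataclass(frozen=True)
class Facility:
    """A service point with provider capacity and a public rating.

    ``capacity`` counts providers (physiatrists) at the site and must be
    positive; ``rating`` is the Google-style satisfaction score on the
    1-5 scale.
    """

    id: str
    region_id: str
    county_id: str
    capacity: float
    rating: float
    x: float = 0.0
    y: float = 0.0

    def __post_init__(self) -> None:
        if not self.capacity > 0:
            raise ValueError(f"facility {self.id!r}: capacity must be > 0")
        if not (1.0 <= self.rating <= 5.0):
            raise ValueError(
                f"facility {self.id!r}: rating {self.rating} outside [1, 5]"
            )


class TravelCosts:
    """Sparse demand->facility route distances in km.

    An absent pair is unreachable (treated as beyond every search radius),
    so sparse matrices are valid input.  The same matrix serves both
    directions: d(i, j) is used for demand->facility and facility->demand.
    """

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None):
        self.entries: dict[tuple[str, str], float] = {}
        if entries:
            for (i, j), d in entries.items():
                self.set(i, j, d)

    def set(self, demand_id: str, facility_id: str, distance_km: float) -> None:
        if distance_km < 0:
            raise ValueError(
                f"distance for ({demand_id!r}, {facility_id!r}) is negative"
            )
        self.entries[(demand_id, facility_id)] = float(distance_km)

    def get(self, demand_id: str, facility_id: str) -> float | None:
        return self.entries.get((demand_id, facility_id))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.entries)

    def matrix(
        self, demand_ids: list[str], facility_ids: list[str]
    ) -> np.ndarray:
        """Dense (n_demand, n_facility) distance array, NaN where absent."""
        out = np.full((len(demand_ids), len(facility_ids)), np.nan)
        fpos = {j: c for c, j in enumerate(facility_ids)}
        dpos = {i: r for r, i in enumerate(demand_ids)}
        for (i, j), d in self.entries.items():
            r = dpos.get(i)
            c = fpos.get(j)
            if r is not None and c is not None:
                out[r, c] = d
        return out


@dataclass(frozen=True)
class DecayParams:
    """Piecewise distance-decay bands.

    With edges (e1, .., eh) the kernel is 1 up to e1, then e_{r-1}/d^{r-1}
    on band r, and 0 beyond eh.  The defaults (3, 15, 30) km give the
    walk / half-hour-drive / hour-drive bands: f = 1, 3/d, 15/d², 0.
    Bands are closed on the right: (-inf, e1], (e1, e2], ..., (eh, inf).
    """

    band_edges: tuple[float, ...] = (3.0, 15.0, 30.0)

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.band_edges)
        if len(edges) < 1:
            raise ValueError("at least one band edge is required")
        if edges[0] <= 0 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("band edges must be positive and strictly increasing")
        object.__setattr__(self, "band_edges", edges)

    @property
    def cutoff(self) -> float:
        """Outermost search radius; beyond it the weight is zero."""
        return self.band_edges[-1]


DEFAULT_DECAY = DecayParams()


def distance_decay(d, params: DecayParams = DEFAULT_DECAY):
    """Distance-decay weight f(d) in [0, 1] for route distance ``d`` km.

    Accepts a scalar or array.  Raises ``ValueError`` on negative input.
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("distance must be nonnegative")
    edges = np.asarray(params.band_edges)
    # band index: 0 for d <= e1, r for e_r < d <= e_{r+1}, len(edges) beyond
    band = np.searchsorted(edges, arr, side="left")
    # searchsorted(side="left") puts d == e_r into band r-1's upper edge
    # position already (e_r itself belongs to the band it closes).
    with np.errstate(divide="ignore"):
        out = np.zeros_like(arr)
        out = np.where(band == 0, 1.0, out)
        for r in range(1, len(edges)):
            sel = band == r
            if np.any(sel):
                out = np.where(sel, edges[r - 1] / arr**r, out)
    if np.isscalar(d) or arr.ndim == 0:
        return float(out)
    return out


def catchment(
    demand_id: str,
    costs: TravelCosts,
    params: DecayParams = DEFAULT_DECAY,
    demand_ids: Iterable[str] | None = None,
) -> set[str]:
    """Facilities within the outermost search radius of a demand point.

    Absent distance entries are unreachable and excluded.  When
    ``demand_ids`` (the known universe of demand identifiers) is given,
    an unknown ``demand_id`` raises ``KeyError``.
    """
    if demand_ids is not None and demand_id not in set(demand_ids):
        raise KeyError(f"unknown demand id {demand_id!r}")
    cut = params.cutoff
    return {
        j
        for (i, j), d in costs.entries.items()
        if i == demand_id and d <= cut
    }


def euclidean_km(x1: float, y1: float, x2: float, y2: float) -> float:
    """Planar distance helper used by the simulator (never by scoring)."""
    return math.hypot(x2 - x1, y2 - y1)
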