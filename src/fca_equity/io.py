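"""Reading and writing the package's table formats.

All tables are UTF-8 comma-delimited CSV with a mandatory header row.
Schemas:

* demand:     ``id,region_id,county_id,population,x_km,y_km``
* facilities: ``id,region_id,county_id,capacity,rating,x_km,y_km``
* distances:  ``demand_id,facility_id,distance_km`` (long/sparse; a missing
  pair is unreachable)
* scores:     ``id,score`` preceded by a ``#`` comment line carrying the
  method label and scale factor, so results are self-describing.

Validation errors carry 1-based data row numbers (header = row 1).  A
GeoJSON FeatureCollection of Point features can be written for demand or
facilities, optionally carrying scores and quintile colors.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .accessibility import AccessibilityResult
from .core import DemandPoint, Facility, TravelCosts

__all__ = [
    "SchemaError",
    "read_demand", "write_demand",
    "read_facilities", "write_facilities",
    "read_distances", "write_distances",
    "read_scores", "write_scores",
    "write_geojson_points",
]


class SchemaError(ValueError):
    """Input table violates its schema; message lists offending rows."""


def _load(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df

def _fail(path, problems: list[str]) -> None:
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))


def read_demand(path) -> list[DemandPoint]:
    df = _load(path, ["id", "region_id", "county_id", "population", "x_km", "y_km"])
    problems, out, seen = [], [], set()
    for n, row in enumerate(df.itertuples(index=False), start=2):
        if row.id in seen:
            problems.append(f"row {n}: duplicate id {row.id!r}")
            continue
        seen.add(row.id)
        try:
            pop = int(row.population)
            if pop < 0:
                raise ValueError
        except (TypeError, ValueError):
            problems.append(f"row {n}: population {row.population!r} is not a "
                            "nonnegative integer")
            continue
        out.append(DemandPoint(row.id, row.region_id, row.county_id, pop,
                               float(row.x_km), float(row.y_km)))
    _fail(path, problems)
    return out


def read_facilities(path) -> list[Facility]:
    df = _load(path, ["id", "region_id", "county_id", "capacity", "rating",
                      "x_km", "y_km"])
    problems, out, seen = [], [], set()
    for n, row in enumerate(df.itertuples(index=False), start=2):
        if row.id in seen:
            problems.append(f"row {n}: duplicate id {row.id!r}")
            continue
        seen.add(row.id)
        try:
            cap, rating = float(row.capacity), float(row.rating)
        except (TypeError, ValueError):
            problems.append(f"row {n}: capacity/rating not numeric")
            continue
        if not cap > 0:
            problems.append(f"row {n}: capacity {cap} must be > 0")
            continue
        if not (1.0 <= rating <= 5.0):
            problems.append(f"row {n}: rating {rating} outside [1, 5]")
            continue
        out.append(Facility(row.id, row.region_id, row.county_id, cap, rating,
                            float(row.x_km), float(row.y_km)))
    _fail(path, problems)
    return out


def read_distances(path) -> TravelCosts:
    df = _load(path, ["demand_id", "facility_id", "distance_km"])
    problems = []
    costs = TravelCosts()
    for n, row in enumerate(df.itertuples(index=False), start=2):
        try:
            d = float(row.distance_km)
            if not d >= 0:  # rejects negatives and NaN
                raise ValueError
        except (TypeError, ValueError):
            problems.append(f"row {n}: distance {row.distance_km!r} is not a "
                            "nonnegative number")
            continue
        costs.set(row.demand_id, row.facility_id, d)
    _fail(path, problems)
    return costs


def write_demand(demand: Iterable[DemandPoint], path) -> None:
    pd.DataFrame(
        [(d.id, d.region_id, d.county_id, d.population, d.x, d.y) for d in demand],
        columns=["id", "region_id", "county_id", "population", "x_km", "y_km"],
    ).to_csv(path, index=False)


def write_facilities(facilities: Iterable[Facility], path) -> None:
    pd.DataFrame(
        [(f.id, f.region_id, f.county_id, f.capacity, f.rating, f.x, f.y)
         for f in facilities],
        columns=["id", "region_id", "county_id", "capacity", "rating",
                 "x_km", "y_km"],
    ).to_csv(path, index=False)


def write_distances(costs: TravelCosts, path) -> None:
    rows = sorted((i, j, d) for (i, j), d in costs.entries.items())
    pd.DataFrame(rows, columns=["demand_id", "facility_id", "distance_km"]
                 ).to_csv(path, index=False)


def write_scores(result: AccessibilityResult, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# method={result.method} scale_factor={result.scale_factor:g}\n")
        fh.write("id,score\n")
        for uid in sorted(result.scores):
            fh.write(f"{uid},{result.scores[uid]!r}\n")


def read_scores(path) -> AccessibilityResult:
    path = Path(path)
    method, scale = "?", 10_000.0
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            key, _, val = tok.partition("=")
            if key == "method":
                method = val
            elif key == "scale_factor":
                scale = float(val)
    df = _load(path, ["id", "score"])
    return AccessibilityResult(
        method, {r.id: float(r.score) for r in df.itertuples(index=False)}, scale
    )


def write_geojson_points(
    path,
    demand: Iterable[DemandPoint] = (),
    facilities: Iterable[Facility] = (),
    scores: Mapping[str, float] | None = None,
    classes: Mapping[str, int] | None = None,
    colors: Mapping[int, str] | None = None,
) -> None:
    """GeoJSON FeatureCollection of Point features (planar km coordinates).

    Demand features carry population and, when given, score / quintile
    class / color properties; facility features carry capacity and rating.
    """
    feats = []
    for d in demand:
        props: dict = {"id": d.id, "kind": "demand", "region_id": d.region_id,
                       "county_id": d.county_id, "population": d.population}
        if scores is not None and d.id in scores:
            props["score"] = scores[d.id]
        if classes is not None and d.id in classes:
            props["quintile"] = classes[d.id]
            if colors is not None:
                props["color"] = colors[classes[d.id]]
        feats.append({"type": "Feature",
                      "geometry": {"type": "Point", "coordinates": [d.x, d.y]},
                      "properties": props})
    for f in facilities:
        feats.append({"type": "Feature",
                      "geometry": {"type": "Point", "coordinates": [f.x, f.y]},
                      "properties": {"id": f.id, "kind": "facility",
                                     "region_id": f.region_id,
                                     "county_id": f.county_id,
                                     "capacity": f.capacity,
                                     "rating": f.rating}})
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats}, indent=1),
        encoding="utf-8",
    )
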