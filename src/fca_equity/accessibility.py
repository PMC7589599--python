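"""Accessibility scoring: regional average, 2SFCA, and three 3SFCA variants.

Five methods share one pipeline:

* **A0** — regional average: providers per head within each administrative
  region, distance ignored and cross-region use forbidden.
* **A1** — two-step floating catchment area (2SFCA).  Step 1 gives every
  facility j a supply-to-demand ratio R_j = S_j / Σ_k P_k f(d_kj) over the
  demand reachable within the 30-km radius; step 2 accumulates
  A_i = Σ_j R_j f(d_ij) over the facilities reachable from i.
* **A2/A3/A4** — three-step FCA (3SFCA): a selection weight (choice
  probability) w_ij first splits each demand point's population across the
  competing facilities in its catchment, deflating the demand each facility
  sees; the same weights then scale the ratios accumulated in step 2.  The
  weight is the decay-weighted facility mass, normalized per demand point:
  mass = capacity S_j (A2), rating V_j (A3), or V_j·S_j (A4).

All scores are scaled per 10,000 persons by default.  Because the weights
are applied symmetrically on both sides, total scored resource is conserved:
Σ_i P_i A_i / scale equals the capacity of every facility with reachable
demand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    DEFAULT_DECAY,
    DecayParams,
    DemandPoint,
    Facility,
    TravelCosts,
    distance_decay,
)

__all__ = [
    "METHODS",
    "METHOD_MODES",
    "SelectionWeights",
    "ServiceRatios",
    "AccessibilityResult",
    "regional_average",
    "selection_weights",
    "facility_service_ratio",
    "accessibility_scores",
    "run_all_methods",
    "county_density",
]

log = logging.getLogger(__name__)

METHODS = ("A0", "A1", "A2", "A3", "A4")

#: choice-probability weighting used by each floating-catchment method
METHOD_MODES = {"A1": "none", "A2": "capacity", "A3": "rating",
                "A4": "capacity_rating"}

_MODES = ("none", "capacity", "rating", "capacity_rating")


@dataclass(frozen=True)
class SelectionWeights:
    """Choice probabilities w_ij of demand point i using facility j.

    ``entries`` holds only in-catchment pairs; every other pair has weight
    zero.  For each demand point with a nonempty catchment the stored
    weights sum to 1.  ``mode`` records the facility mass used: capacity
    (K_ij), rating (V_ij), or their product (K^V_ij); ``none`` is the
    implicit all-ones weighting of plain 2SFCA.
    """

    mode: str
    entries: Mapping[tuple[str, str], float]


@dataclass(frozen=True)
class ServiceRatios:
    """Step-1 supply-to-weighted-demand ratios R_j.

    Facilities with zero weighted reachable demand have no defined ratio;
    they are listed in ``flagged`` and excluded from step 2.
    """

    ratios: Mapping[str, float]
    flagged: frozenset[str]


@dataclass(frozen=True)
class AccessibilityResult:
    """Per-demand-point scores A_i for one method, per ``scale_factor`` persons."""

    method: str
    scores: Mapping[str, float]
    scale_factor: float = 10_000.0


class _Workspace:
    """Shared dense arrays for one (demand, facilities, costs) instance."""

    def __init__(
        self,
        demand: Sequence[DemandPoint],
        facilities: Sequence[Facility],
        costs: TravelCosts,
        params: DecayParams,
    ):
        self.demand = list(demand)
        self.facilities = list(facilities)
        self.demand_ids = [d.id for d in self.demand]
        self.facility_ids = [f.id for f in self.facilities]
        _check_unique(self.demand_ids, "demand")
        _check_unique(self.facility_ids, "facility")
        self.P = np.array([d.population for d in self.demand], dtype=float)
        self.S = np.array([f.capacity for f in self.facilities], dtype=float)
        self.V = np.array([f.rating for f in self.facilities], dtype=float)
        D = costs.matrix(self.demand_ids, self.facility_ids)
        reach = np.isfinite(D) & (D <= params.cutoff)
        self.F = np.zeros_like(D)
        if reach.any():
            self.F[reach] = distance_decay(D[reach], params)
        self.reach = reach

    def mass(self, mode: str) -> np.ndarray:
        if mode == "none":
            return np.ones_like(self.S)
        if mode == "capacity":
            return self.S
        if mode == "rating":
            return self.V
        if mode == "capacity_rating":
            return self.S * self.V
        raise ValueError(f"unknown selection mode {mode!r}")

    def weight_matrix(self, mode: str) -> np.ndarray:
        """Row-normalized w_ij; zero rows for empty catchments.

        mode='none' returns the catchment indicator (implicit weight 1
        per reachable facility), not a probability.
        """
        if mode == "none":
            return self.reach.astype(float)
        num = self.F * self.mass(mode)[None, :]
        tot = num.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            W = np.where(tot > 0, num / np.where(tot > 0, tot, 1.0), 0.0)
        return W

    def service_ratios(self, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """R_j = S_j / Σ_k w_kj P_k f(d_kj); NaN where load is zero."""
        load = (W * self.P[:, None] * self.F).sum(axis=0)
        ok = load > 0
        R = np.full_like(self.S, np.nan)
        R[ok] = self.S[ok] / load[ok]
        return R, ok


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dup = set(), set()
        for i in ids:
            (dup if i in seen else seen).add(i)
        raise ValueError(f"duplicate {what} ids: {sorted(dup)}")


def regional_average(
    demand: Iterable[DemandPoint],
    facilities: Iterable[Facility],
    scale: float = 10_000.0,
) -> AccessibilityResult:
    """Method A0: capacity per head within each region, ignoring distance.

    Every demand point in region i scores scale · Σ S_j / Σ P over the
    region's own facilities and population.  A region with population zero
    but facilities present is an undefined ratio: it is reported as 0 with
    a warning.  Facilities whose region matches no demand region are
    orphans — logged and excluded.
    """
    demand = list(demand)
    pop_by_region: dict[str, float] = {}
    for dp in demand:
        pop_by_region[dp.region_id] = pop_by_region.get(dp.region_id, 0.0) + dp.population
    cap_by_region: dict[str, float] = {}
    for fac in facilities:
        if fac.region_id not in pop_by_region:
            log.warning("facility %s in region %s matches no demand region; "
                        "excluded from A0", fac.id, fac.region_id)
            continue
        cap_by_region[fac.region_id] = cap_by_region.get(fac.region_id, 0.0) + fac.capacity
    scores: dict[str, float] = {}
    for dp in demand:
        cap = cap_by_region.get(dp.region_id, 0.0)
        pop = pop_by_region[dp.region_id]
        if pop == 0:
            if cap > 0:
                log.warning("region %s has facilities but zero population; "
                            "A0 score set to 0", dp.region_id)
            scores[dp.id] = 0.0
        else:
            scores[dp.id] = scale * cap / pop
    return AccessibilityResult("A0", scores, scale)


def county_density(
    demand: Iterable[DemandPoint],
    facilities: Iterable[Facility],
    scale: float = 10_000.0,
) -> dict[str, float]:
    """County-level crude density: scale · Σ capacity / Σ population.

    This is the headline providers-per-10,000 figure computed directly at
    county level.  It generally differs from the county mean of town-level
    A0 scores (an unweighted average of per-town ratios); both are exposed
    because published county tables mix the two.
    """
    pop: dict[str, float] = {}
    cap: dict[str, float] = {}
    for dp in demand:
        pop[dp.county_id] = pop.get(dp.county_id, 0.0) + dp.population
    for fac in facilities:
        cap[fac.county_id] = cap.get(fac.county_id, 0.0) + fac.capacity
    return {
        c: (scale * cap.get(c, 0.0) / p if p > 0 else 0.0)
        for c, p in pop.items()
    }


def selection_weights(
    demand: Sequence[DemandPoint],
    facilities: Sequence[Facility],
    costs: TravelCosts,
    params: DecayParams = DEFAULT_DECAY,
    mode: str = "capacity_rating",
) -> SelectionWeights:
    """Choice probabilities over each demand point's 30-km catchment.

    w_ij = m_j f(d_ij) / Σ_{k in catchment(i)} m_k f(d_ik) with facility
    mass m per ``mode``.  Demand points with empty catchments get no
    entries.
    """
    if mode not in ("capacity", "rating", "capacity_rating"):
        raise ValueError(f"mode must be one of capacity/rating/capacity_rating, got {mode!r}")
    ws = _Workspace(demand, facilities, costs, params)
    W = ws.weight_matrix(mode)
    entries = {
        (ws.demand_ids[r], ws.facility_ids[c]): float(W[r, c])
        for r, c in zip(*np.nonzero(W))
    }
    return SelectionWeights(mode, entries)


def facility_service_ratio(
    demand: Sequence[DemandPoint],
    facilities: Sequence[Facility],
    costs: TravelCosts,
    params: DecayParams = DEFAULT_DECAY,
    weights: SelectionWeights | None = None,
) -> ServiceRatios:
    """Step 1: each facility's supply-to-weighted-demand ratio R_j.

    With ``weights=None`` every reachable demand point counts fully
    (2SFCA); otherwise the selection weights deflate the demand.  The
    load on facility j is Σ_k w_kj P_k f(d_kj) over demand within the
    search radius; facilities with zero load are flagged.
    """
    ws = _Workspace(demand, facilities, costs, params)
    W = ws.weight_matrix("none" if weights is None else weights.mode)
    R, ok = ws.service_ratios(W)
    flagged = frozenset(j for j, good in zip(ws.facility_ids, ok) if not good)
    for j in sorted(flagged):
        log.warning("facility %s has no weighted reachable demand; "
                    "excluded from step 2", j)
    ratios = {j: float(r) for j, r, good in zip(ws.facility_ids, R, ok) if good}
    return ServiceRatios(ratios, flagged)


def accessibility_scores(
    method: str,
    demand: Sequence[DemandPoint],
    facilities: Sequence[Facility],
    costs: TravelCosts,
    params: DecayParams = DEFAULT_DECAY,
    scale: float = 10_000.0,
) -> AccessibilityResult:
    """Floating-catchment accessibility A_i for one of methods A1-A4.

    A_i = scale · Σ_{j in catchment(i)} w_ij R_j f(d_ij), with w_ij = 1
    for A1.  Demand points with empty catchments score 0.
    """
    if method not in METHOD_MODES:
        raise ValueError(f"method must be one of {sorted(METHOD_MODES)}, got {method!r}")
    ws = _Workspace(demand, facilities, costs, params)
    return _score(ws, method, scale)


def _score(ws: _Workspace, method: str, scale: float) -> AccessibilityResult:
    W = ws.weight_matrix(METHOD_MODES[method])
    R, ok = ws.service_ratios(W)
    if not ok.all():
        for j in sorted(np.array(ws.facility_ids)[~ok]):
            log.warning("facility %s has no weighted reachable demand; "
                        "excluded from step 2 (%s)", j, method)
    Rsafe = np.where(ok, R, 0.0)
    A = scale * (W * ws.F * Rsafe[None, :]).sum(axis=1)
    return AccessibilityResult(
        method, dict(zip(ws.demand_ids, A.tolist())), scale
    )


def run_all_methods(
    demand: Sequence[DemandPoint],
    facilities: Sequence[Facility],
    costs: TravelCosts,
    params: DecayParams = DEFAULT_DECAY,
    scale: float = 10_000.0,
) -> dict[str, AccessibilityResult]:
    """Compute A0-A4 in one pass, sharing decay and catchment arrays."""
    out = {"A0": regional_average(demand, facilities, scale)}
    ws = _Workspace(demand, facilities, costs, params)
    for method in ("A1", "A2", "A3", "A4"):
        out[method] = _score(ws, method, scale)
    return out
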