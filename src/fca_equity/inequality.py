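"""Equity assessment of accessibility scores.

Per-group summary statistics, the Lorenz curve and population-weighted Gini
coefficient of the score distribution, quintile classification for mapping,
and a three-stage policy-prioritization rule for flagging counties with
concentrated low access.

The Gini treats the accessibility score A_i as per-capita "income": the
Lorenz x-axis cumulates population shares and the y-axis cumulates resource
volume A_i·P_i shares, with units sorted ascending by score.  G is twice
the area between the equality diagonal and the curve, integrated with the
trapezoidal rule on the curve's vertices.  An unweighted variant (uniform
unit shares) is available behind ``weighted=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GroupSummary",
    "LorenzCurve",
    "GINI_CATEGORIES",
    "QUINTILE_COLORS",
    "summary_stats",
    "lorenz_points",
    "gini",
    "gini_category",
    "quintile_classes",
    "prioritize",
]

log = logging.getLogger(__name__)

#: five-level interpretation scale for the Gini coefficient
GINI_CATEGORIES = (
    "highly_equitable",   # G < 0.2
    "equitable",          # 0.2 <= G < 0.3
    "bearable",           # 0.3 <= G < 0.4
    "median_inequality",  # 0.4 <= G <= 0.6
    "high_inequality",    # G > 0.6
)

#: map colors for quintile classes 1 (lowest scores) .. 5 (highest)
QUINTILE_COLORS = {1: "red", 2: "orange", 3: "green",
                   4: "lightblue", 5: "darkblue"}


@dataclass(frozen=True)
class GroupSummary:
    """Distributional summary of one group's (county's) town scores."""

    group_id: str
    n_units: int
    mean: float
    median: float
    sd: float
    min: float
    max: float
    median_minus_mean: float
    gini: float
    gini_category: str


@dataclass(frozen=True)
class LorenzCurve:
    """Cumulative population share (x) vs cumulative resource share (y)."""

    points: tuple[tuple[float, float], ...]


def summary_stats(
    scores: Mapping[str, float],
    grouping: Mapping[str, str],
    populations: Mapping[str, float] | None = None,
    weighted: bool = True,
) -> list[GroupSummary]:
    """Per-group mean/median/sd/min/max, median−mean, and Gini.

    ``grouping`` maps every demand id to its group (county).  sd is the
    sample standard deviation (ddof=1; 0 for singleton groups); the median
    of an even count is the midpoint of the two central values.  The Gini
    is population-weighted when ``populations`` is given and ``weighted``
    is true, otherwise unweighted.  Empty groups are excluded with a
    warning.
    """
    missing = set(scores) - set(grouping)
    if missing:
        raise KeyError(f"demand ids without a group: {sorted(missing)[:5]}")
    groups: dict[str, list[str]] = {}
    for uid in scores:
        groups.setdefault(grouping[uid], []).append(uid)
    out = []
    for gid in sorted(groups):
        ids = groups[gid]
        if not ids:  # pragma: no cover - empty groups cannot arise from dict build
            log.warning("group %s has no units; excluded", gid)
            continue
        vals = np.array([scores[i] for i in ids], dtype=float)
        g = gini(
            {i: scores[i] for i in ids},
            None if populations is None else {i: populations[i] for i in ids},
            weighted=weighted,
        )
        mean = float(vals.mean())
        med = float(np.median(vals))
        out.append(
            GroupSummary(
                group_id=gid,
                n_units=len(ids),
                mean=mean,
                median=med,
                sd=float(vals.std(ddof=1)) if len(ids) > 1 else 0.0,
                min=float(vals.min()),
                max=float(vals.max()),
                median_minus_mean=med - mean,
                gini=g,
                gini_category=gini_category(g),
            )
        )
    return out


def _sorted_shares(
    scores: Mapping[str, float],
    populations: Mapping[str, float] | None,
    weighted: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit shares (population and resource volume) sorted ascending by score."""
    if not scores:
        raise ValueError("at least one unit is required")
    ids = sorted(scores, key=lambda i: (scores[i], i))  # ties by id: deterministic
    a = np.array([scores[i] for i in ids], dtype=float)
    if weighted:
        if populations is None:
            raise ValueError("populations are required for the weighted Lorenz curve")
        p = np.array([populations[i] for i in ids], dtype=float)
        if p.sum() <= 0:
            raise ValueError("total population must be positive")
    else:
        p = np.ones_like(a)
    p = p / p.sum()
    vol = a * p
    return p, vol


def lorenz_points(
    scores: Mapping[str, float],
    populations: Mapping[str, float] | None = None,
    weighted: bool = True,
) -> LorenzCurve:
    """Lorenz curve of accessibility: starts at (0,0), ends at (1,1).

    Units are sorted ascending by score (ties broken by id); x cumulates
    population shares, y cumulates resource-volume (A_i·P_i) shares.  When
    every unit scores 0 the curve degenerates to y ≡ 0 (and ends at (1,0)).
    """
    p, vol = _sorted_shares(scores, populations, weighted)
    x = np.concatenate([[0.0], np.cumsum(p)])
    x[-1] = 1.0  # guard against float drift in the last vertex
    tot = vol.sum()
    if tot > 0:
        y = np.concatenate([[0.0], np.cumsum(vol) / tot])
        y[-1] = 1.0
    else:
        y = np.zeros_like(x)
    return LorenzCurve(tuple(zip(x.tolist(), y.tolist())))


def gini(
    scores: Mapping[str, float],
    populations: Mapping[str, float] | None = None,
    weighted: bool = True,
) -> float:
    """Gini coefficient: twice the area between diagonal and Lorenz curve.

    0 is complete equality, values near 1 maximal concentration.  Computed
    by the trapezoidal rule over the curve's vertices and clipped to
    [0, 1].  A distribution with zero total resource is defined as G = 0.
    """
    curve = lorenz_points(scores, populations, weighted)
    pts = np.asarray(curve.points)
    x, y = pts[:, 0], pts[:, 1]
    if y[-1] == 0.0:
        return 0.0
    area_under = float(np.trapezoid(y, x))
    return float(np.clip(1.0 - 2.0 * area_under, 0.0, 1.0))


def gini_category(g: float) -> str:
    """Five-level label for a Gini coefficient.

    Bands: <0.2 highly equitable; 0.2–0.3 equitable; 0.3–0.4 bearable;
    0.4–0.6 median inequality (both ends inclusive); >0.6 high inequality.
    """
    if not (0.0 <= g <= 1.0):
        raise ValueError(f"gini must lie in [0, 1], got {g}")
    if g > 0.6:
        return "high_inequality"
    if g >= 0.4:
        return "median_inequality"
    if g >= 0.3:
        return "bearable"
    if g >= 0.2:
        return "equitable"
    return "highly_equitable"


def quintile_classes(scores: Mapping[str, float]) -> dict[str, int]:
    """Quintile class 1..5 per unit by percentile rank of its score.

    Class k holds units whose percentile rank (share of units scoring at
    or below theirs) falls in ((k−1)·20%, k·20%]; tied scores share a
    class.  With all scores equal there is nothing to classify: every unit
    goes to class 1 with a warning.  With fewer than 5 units each unit is
    its own class by ascending rank.
    """
    ids = sorted(scores, key=lambda i: (scores[i], i))
    n = len(ids)
    if n == 0:
        return {}
    vals = np.array([scores[i] for i in ids], dtype=float)
    if n < 5:
        return {uid: k + 1 for k, uid in enumerate(ids)}
    if vals.min() == vals.max():
        log.warning("all %d scores identical; degenerate distribution, "
                    "every unit assigned class 1", n)
        return {uid: 1 for uid in ids}
    # max-rank of each unit's score / n = percentile rank; ceil into 5 bins
    upper = np.searchsorted(vals, vals, side="right")  # count of scores <= value
    ranks = upper / n
    classes = np.ceil(ranks * 5 - 1e-12).astype(int)
    classes = np.clip(classes, 1, 5)
    return dict(zip(ids, classes.tolist()))


def prioritize(
    summaries: Iterable[GroupSummary],
    national: GroupSummary,
) -> dict[str, int | None]:
    """Three-stage improvement priority per group.

    Stage 1: median below mean (concentrated low access) *and* Gini in the
    median- or high-inequality band.  Stage 2: median below mean and group
    mean below the national mean (stage-1 groups excluded).  Stage 3: any
    remaining group with median below mean.  ``None`` otherwise.
    """
    out: dict[str, int | None] = {}
    for s in summaries:
        low_half = s.median_minus_mean < 0
        if low_half and s.gini_category in ("median_inequality", "high_inequality"):
            out[s.group_id] = 1
        elif low_half and s.mean < national.mean:
            out[s.group_id] = 2
        elif low_half:
            out[s.group_id] = 3
        else:
            out[s.group_id] = None
    return out
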