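"""Independent per-definition oracles used to cross-check the vectorized code.

Everything here is written as plain double loops straight from the method
definitions: step 1 computes each facility's supply-to-weighted-demand ratio,
step 2 accumulates those ratios over each demand point's catchment.  No code
is shared with the package implementation.
"""

from __future__ import annotations


def decay_oracle(d: float) -> float:
    """Three-band distance-decay kernel, literal transcription."""
    if d < 0:
        raise ValueError("negative distance")
    if d <= 3.0:
        return 1.0
    if d <= 15.0:
        return 3.0 / d
    if d <= 30.0:
        return 15.0 / d**2
    return 0.0


def _pairs(costs):
    """Accept either a mapping {(i, j): d} or an object with .entries."""
    if hasattr(costs, "entries"):
        return dict(costs.entries)
    return dict(costs)


def choice_weights_oracle(demand, facilities, costs, mode):
    """w_ij = m_j f(d_ij) / sum_k m_k f(d_ik) over i's 30-km catchment."""
    dist = _pairs(costs)
    out = {}
    if mode == "none":
        # plain 2SFCA: implicit weight 1 for every in-catchment facility
        for dp in demand:
            for fac in facilities:
                d = dist.get((dp.id, fac.id))
                if d is not None and d <= 30.0:
                    out[(dp.id, fac.id)] = 1.0
        return out
    for dp in demand:
        num = {}
        for fac in facilities:
            d = dist.get((dp.id, fac.id))
            if d is None or d > 30.0:
                continue
            if mode == "capacity":
                m = fac.capacity
            elif mode == "rating":
                m = fac.rating
            elif mode == "capacity_rating":
                m = fac.capacity * fac.rating
            else:
                raise ValueError(mode)
            num[fac.id] = m * decay_oracle(d)
        tot = sum(num.values())
        if tot > 0:
            for j, v in num.items():
                out[(dp.id, j)] = v / tot
    return out


def service_ratio_oracle(demand, facilities, costs, mode):
    """R_j = S_j / sum_k w_kj P_k f(d_kj); None when no weighted demand."""
    dist = _pairs(costs)
    w = choice_weights_oracle(demand, facilities, costs, mode)
    ratios = {}
    for fac in facilities:
        load = 0.0
        for dp in demand:
            d = dist.get((dp.id, fac.id))
            if d is None or d > 30.0:
                continue
            load += w.get((dp.id, fac.id), 0.0) * dp.population * decay_oracle(d)
        ratios[fac.id] = fac.capacity / load if load > 0 else None
    return ratios


def accessibility_oracle(method, demand, facilities, costs, scale=10_000.0):
    """A_i = scale * sum_j w_ij R_j f(d_ij) for methods A1-A4."""
    mode = {"A1": "none", "A2": "capacity", "A3": "rating",
            "A4": "capacity_rating"}[method]
    dist = _pairs(costs)
    w = choice_weights_oracle(demand, facilities, costs, mode)
    ratios = service_ratio_oracle(demand, facilities, costs, mode)
    scores = {}
    for dp in demand:
        acc = 0.0
        for fac in facilities:
            d = dist.get((dp.id, fac.id))
            if d is None or d > 30.0:
                continue
            r = ratios[fac.id]
            if r is None:
                continue
            acc += w.get((dp.id, fac.id), 0.0) * r * decay_oracle(d)
        scores[dp.id] = scale * acc
    return scores


def gini_mad_oracle(scores, populations):
    """Population-weighted mean-absolute-difference Gini.

    G = sum_i sum_j p_i p_j |a_i - a_j| / (2 abar), p = population shares,
    abar = population-weighted mean score.
    """
    ids = list(scores)
    ptot = float(sum(populations[i] for i in ids))
    p = {i: populations[i] / ptot for i in ids}
    abar = sum(p[i] * scores[i] for i in ids)
    if abar == 0:
        return 0.0
    acc = 0.0
    for i in ids:
        for j in ids:
            acc += p[i] * p[j] * abs(scores[i] - scores[j])
    return acc / (2.0 * abar)
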