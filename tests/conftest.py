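import numpy as np
import pytest

from fca_equity import LandscapeConfig, generate_landscape


SMALL = dict(
    n_counties=5,
    towns_per_county=(8, 12),
    n_urban_centers=2,
    n_facilities=20,
    extent_km=(80.0, 120.0),
)


def small_landscape(seed: int, **overrides):
    """~50-town / 20-facility landscape for property suites."""
    cfg = LandscapeConfig(random_seed=seed, **{**SMALL, **overrides})
    return generate_landscape(cfg)


def tiny_random_instance(rng: np.random.Generator, n_demand=None, n_facility=None):
    """Hand-rolled instance (<= 20 x 10) independent of the generator,
    for brute-force oracle comparisons."""
    from fca_equity import DemandPoint, Facility, TravelCosts

    nd = n_demand or int(rng.integers(2, 21))
    nf = n_facility or int(rng.integers(1, 11))
    demand = [
        DemandPoint(f"d{i}", f"d{i}", f"c{i % 3}", int(rng.integers(0, 5000)))
        for i in range(nd)
    ]
    facilities = [
        Facility(f"f{j}", f"d{j % nd}", f"c{j % 3}",
                 capacity=float(rng.integers(1, 6)),
                 rating=float(np.round(rng.uniform(1.0, 5.0), 2)))
        for j in range(nf)
    ]
    costs = TravelCosts()
    for i in range(nd):
        for j in range(nf):
            if rng.random() < 0.8:  # leave some pairs unreachable
                costs.set(f"d{i}", f"f{j}", float(np.round(rng.uniform(0, 40), 3)))
    return demand, facilities, costs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
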