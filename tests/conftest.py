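import logging

import numpy as np
import pytest

from twostepfca import CityParams, Facility, Region, generate_city

# zero-demand-facility warnings are expected in randomised instances
logging.getLogger("twostepfca.accessibility").setLevel(logging.ERROR)


def random_instance(rng, n_regions=None, n_facilities=None, max_time=20.0):
    """A random small accessibility problem: regions, facilities, times."""
    nr = n_regions or int(rng.integers(3, 11))
    nf = n_facilities or int(rng.integers(1, 6))
    regions = [
        Region(
            id=f"R{i}",
            centroid=(float(rng.uniform(0, 1000)), float(rng.uniform(0, 1000))),
            severity_counts=tuple(int(v) for v in rng.integers(0, 50, size=4)),
        )
        for i in range(nr)
    ]
    facilities = [
        Facility(
            id=f"H{j}",
            location=(float(rng.uniform(0, 1000)), float(rng.uniform(0, 1000))),
            beds=int(rng.integers(55, 751)),
        )
        for j in range(nf)
    ]
    times = rng.uniform(0, max_time, size=(nr, nf))
    # sprinkle unreachable pairs
    mask = rng.random((nr, nf)) < 0.05
    times[mask] = np.inf
    return regions, facilities, times


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def default_city():
    """One default-parameter synthetic city shared across tests."""
    return generate_city(CityParams(seed=11))


@pytest.fixture(scope="session")
def compact_city_params():
    """A city small enough (in travel time) that every pair is within 5 min."""

    def make(seed: int) -> CityParams:
        return CityParams(
            n_regions=9,
            grid_extent=1200.0,
            n_facilities=3,
            total_population=20_000,
            disability_rate=0.02,
            seed=seed,
        )

    return make
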