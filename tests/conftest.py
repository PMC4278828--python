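import numpy as np
import pytest

import sdmuq as q


@pytest.fixture(scope="session")
def small_geometry():
    """40x40 1-km projected grid used by fast unit tests."""
    return q.GridGeometry(40, 40, 0.0, 40_000.0, 1000.0, q.CRSKind.projected_metric)


@pytest.fixture(scope="session")
def small_landscape(small_geometry):
    params = q.LandscapeParams(geometry=small_geometry, rng_seed=42)
    return q.generate_landscape(params)


@pytest.fixture(scope="session")
def small_stack(small_landscape):
    return small_landscape[0]


@pytest.fixture(scope="session")
def small_errors(small_landscape):
    return small_landscape[1]


@pytest.fixture(scope="session")
def small_bioclim(small_stack):
    return q.derive_bioclim(small_stack)


@pytest.fixture(scope="session")
def small_region_mask(small_stack):
    return q.Grid(
        small_stack.geometry,
        np.zeros_like(small_stack.mask, dtype=float),
        small_stack.mask.copy(),
    )


@pytest.fixture(scope="session")
def small_occurrences(small_bioclim):
    return q.generate_occurrences(q.DEFAULT_NICHE, small_bioclim, 120, rng_seed=7)


@pytest.fixture(scope="session")
def small_background(small_region_mask):
    return q.sample_background(small_region_mask, 800, 11)


@pytest.fixture(scope="session")
def default_landscape():
    """The default 100x100 study fixture; session-scoped because it is reused widely."""
    params = q.LandscapeParams(rng_seed=0)
    return q.generate_landscape(params)


@pytest.fixture(scope="session")
def default_bioclim(default_landscape):
    return q.derive_bioclim(default_landscape[0])


@pytest.fixture(scope="session")
def default_region_mask(default_landscape):
    stack = default_landscape[0]
    return q.Grid(stack.geometry, np.zeros_like(stack.mask, dtype=float), stack.mask.copy())
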