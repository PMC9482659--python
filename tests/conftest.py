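import numpy as np
import pytest

import endemia as e


@pytest.fixture(scope="session")
def grid16():
    return e.GridSpec(16, 16, 0.5, (0.0, 10.0))


@pytest.fixture(scope="session")
def world16(grid16):
    return e.generate_world(grid16, n_countries=2, ecoregions_per_country=2, seed=11)


@pytest.fixture(scope="session")
def stack16(grid16):
    return e.generate_climate(grid16, autocorr_length=2.0, cross_corr=0.6, seed=11)


def make_stack(grid, layers):
    """Build a ClimateStack from a dict of 2-D arrays (test helper)."""
    return e.ClimateStack(grid, {k: np.asarray(v, dtype=float) for k, v in layers.items()})


@pytest.fixture(scope="session")
def study_run():
    """The study-conditions pipeline run: 30 virtual species on a 60x60 grid,
    noise-free occurrences, the full five-algorithm ensemble. Shared across
    the recovery and scenario-ordering tests."""
    return e.run_pipeline(e.RunConfig(seed=1))
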