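import numpy as np
import pytest

from inflamnet import SimulationParams, aging_preset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_params(**overrides) -> SimulationParams:
    """Small, fast parameter set for unit tests; overridable per test."""
    defaults = dict(grid_rows=25, grid_cols=25, n_iterations=80, stimulus=0.8,
                    aging=aging_preset("N"), seed=0)
    defaults.update(overrides)
    return SimulationParams(**defaults)


@pytest.fixture(scope="session")
def reference_run():
    """One deterministic mid-size stimulated run shared across test modules."""
    from inflamnet import run

    params = SimulationParams(grid_rows=40, grid_cols=40, n_iterations=250,
                              stimulus=0.8, aging=aging_preset("N"), seed=3)
    return run(params)
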