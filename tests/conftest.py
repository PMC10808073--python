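import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from exoatlas import SimConfig, simulate_atlas

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced atlas for unit tests (fast, same structure as default)."""
    return SimConfig(
        n_cells_per_type=60,
        n_genes=600,
        n_junk_cells=15,
        n_induced_genes=20,
        n_tip_genes=8,
        n_organellar=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_atlas(small_cfg):
    return simulate_atlas(small_cfg)


@pytest.fixture(scope="session")
def default_atlas():
    """A full-size atlas at the study conditions, seed 7."""
    return simulate_atlas(SimConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
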