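import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from provmap.simulate import SimulationConfig, build_reference

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Desk-scale simulation world: ~65 kb host genome, 4 kb provirus, 12x."""
    return SimulationConfig(
        seed=11,
        placed_lengths=(30_000, 30_000),
        unplaced_lengths=(5_000,),
        provirus_len=4_000,
        utr_len=400,
        depth=12.0,
    )


@pytest.fixture(scope="session")
def small_refset(small_cfg):
    return build_reference(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
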