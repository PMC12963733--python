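import pytest
from hypothesis import HealthCheck, settings

from ceranet.config import SimConfig
from ceranet.simulate import generate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_sim_config(**overrides) -> SimConfig:
    """A scaled-down study that still exercises every planted structure."""
    defaults = dict(
        seed=11,
        n_mrna=60,
        n_lncrna=30,
        n_mirna=40,
        n_planted_triads=8,
        n_replicates_per_condition=4,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return small_sim_config()


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)
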