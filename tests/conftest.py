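import pytest
from hypothesis import HealthCheck, settings

from phyloloc import synthetic_data as sd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """A compact full synthetic dataset shared across module tests."""
    params = sd.SimulationParams(
        n_genes=250,
        n_edges=600,
        n_paralog_pairs=40,
        sequence_length=50,
        seed=101,
    )
    return sd.simulate(params)
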