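import pytest
from hypothesis import HealthCheck, settings

from nirglucose.simulate import SynthConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """The default interval-design acquisition campaign at seed 0."""
    return generate_dataset(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def samples(default_dataset):
    return default_dataset[0]


@pytest.fixture(scope="session")
def finger_records(samples):
    return samples[samples["site"] == "finger"].reset_index(drop=True)
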