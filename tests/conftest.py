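import pytest
from hypothesis import HealthCheck, settings

from hetpath.fixtures import (
    default_random_spec,
    generate_hetnet,
    hetionet_metagraph,
    toy_fixtures,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toys():
    return toy_fixtures()


@pytest.fixture(scope="session")
def toy_gig(toys):
    return toys["toy-GiG"]


@pytest.fixture(scope="session")
def toy_cd(toys):
    return toys["toy-CD"]


@pytest.fixture(scope="session")
def random_store():
    return generate_hetnet(default_random_spec(seed=0, n_nodes=14, density=0.2))


@pytest.fixture(scope="session")
def hetionet():
    return hetionet_metagraph()
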