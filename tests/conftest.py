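import pytest

from mgnet import SimConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """One default synthetic world, shared read-only across tests."""
    return generate_world(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_world_files(tmp_path_factory):
    """The same world written to disk, for reader/CLI round-trips."""
    out = tmp_path_factory.mktemp("world")
    return generate_world(SimConfig(seed=1), out)
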