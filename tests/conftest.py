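import pytest

from milksieve import (
    SimulationConfig,
    generate_references,
    generate_sample,
    load_default_model,
)


@pytest.fixture(scope="session")
def model():
    return load_default_model()


@pytest.fixture(scope="session")
def sim():
    """Default synthetic fixture: bundle, reads and truth manifest (seed 1)."""
    config = SimulationConfig(seed=1)
    bundle, manifest = generate_references(config)
    reads, manifest = generate_sample(config, bundle, manifest)
    return config, bundle, reads, manifest
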