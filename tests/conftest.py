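import pytest

from temnet.synthetic import (
    default_planted_design,
    generate_response_dataset,
    paperlike_network,
)


@pytest.fixture(scope="session")
def paperlike():
    return paperlike_network()


@pytest.fixture(scope="session")
def planted_dataset():
    """Default planted design at seed 1: (receptor table, cytokine table, truth)."""
    return generate_response_dataset(default_planted_design(seed=1))


@pytest.fixture(scope="session")
def noiseless_dataset():
    return generate_response_dataset(default_planted_design(noise_sd=0.0, seed=2))
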