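import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=60)
settings.load_profile("deterministic")

from pfas_screen.suspects import build_suspect_list
from pfas_screen.synthetic import SimulationConfig, default_suspect_records, simulate_dataset


@pytest.fixture(scope="session")
def default_suspects():
    return build_suspect_list(default_suspect_records())


@pytest.fixture(scope="session")
def clean_dataset(default_suspects):
    """Noiseless default simulation: the reference recovery condition."""
    return simulate_dataset(SimulationConfig(seed=1), default_suspects)
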