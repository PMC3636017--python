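import numpy as np
import pytest

from interphyte.simulate import SimulationConfig, simulate_reference_sets


def small_config(seed: int = 1, **overrides) -> SimulationConfig:
    """A desk-scale simulation: enough sequence to exercise every stage."""
    kw = dict(
        seed=seed,
        n_parasite_transcripts=60,
        n_host_transcripts=30,
        n_contaminant_unigenes=10,
        n_nonplant_unigenes=6,
        n_unknown_unigenes=8,
        transcript_length_range=(250, 900),
        n_read_pairs=400,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@pytest.fixture(scope="session")
def config():
    return small_config()


@pytest.fixture(scope="session")
def refs(config):
    return simulate_reference_sets(config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
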