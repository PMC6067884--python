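import numpy as np
import pytest

from mycofly import SimConfig, simulate_references


@pytest.fixture
def small_config() -> SimConfig:
    return SimConfig(
        seed=11,
        n_host_transcripts=10,
        n_pathogen_transcripts=6,
        n_contaminant_seqs=3,
        transcript_length_range=(400, 800),
        n_flies=8,
        recording_hr=120.0,
    )


@pytest.fixture
def small_refset(small_config):
    refset, provenance = simulate_references(small_config)
    return refset


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
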