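import numpy as np
import pytest
from hypothesis import settings

from modaudit import SimulationConfig, Transcript, generate_transcriptome, simulate_site_table

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_ref():
    """Three short transcripts with known C positions for hand checks."""
    return [
        Transcript("tx1", "AAGCTAAGCTTC"),
        Transcript("tx2", "CACGCTACCCA"),
        Transcript("tx3", "TTTTT"),
    ]


@pytest.fixture
def sim_small():
    """A small planted-bias sample: reference, sites and truth table."""
    cfg = SimulationConfig(n_transcripts=5, length_mean=400, seed=11)
    ref = generate_transcriptome(cfg)
    sites, truth = simulate_site_table(ref, cfg)
    return ref, sites, truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(20230)
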