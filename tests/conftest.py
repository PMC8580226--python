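import numpy as np
import pytest

from skincomet import pipeline, synth


@pytest.fixture(scope="session")
def small_panel():
    """A small synthetic reference panel: 5 genomes, 3 planted families,
    short proteins, a couple of decoys per genome."""
    proteomes, truth = synth.simulate_panel(
        n_genomes=5, n_families=3, seq_len=80, decoys_per_genome=2, seed=11)
    return proteomes, truth


@pytest.fixture(scope="session")
def small_models(small_panel):
    proteomes, _ = small_panel
    return pipeline.build_models_from_panel(proteomes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
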