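import numpy as np
import pytest

from agedrift import (ModelConfig, SimulationConfig, build_vocabulary,
                      encode_study, init_model, simulate_corpus, train)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=30, n_cells=240, n_age_bins=5, n_tissues=2, n_cell_types=2,
        diseased_fraction=0.3, frac_dissipative=0.2, n_modules=4, seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_corpus(small_config)


@pytest.fixture(scope="session")
def small_vocab(small_study):
    return build_vocabulary(small_study, n_bins=4)


@pytest.fixture(scope="session")
def small_tokens(small_study, small_vocab):
    return encode_study(small_study, small_vocab)


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(d=16, n_layers=1, n_heads=2, d_ff=32, epochs=2,
                       batch_size=32, seed=3)


@pytest.fixture(scope="session")
def tiny_trained(small_study, small_vocab, small_tokens, tiny_model_config):
    """A small model trained briefly on the small corpus (shared across tests)."""
    model = init_model(small_vocab, small_tokens.shape[1], tiny_model_config)
    model, trace = train(model, small_tokens, tiny_model_config)
    return model, trace
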