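import numpy as np
import pytest
from hypothesis import settings

from medtagger.corpus import build_vocabulary
from medtagger.network import ModelConfig
from medtagger.synthetic import GeneratorConfig, generate_domain_pair

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_pair():
    """A small seeded (general, target) corpus pair shared across tests."""
    cfg = GeneratorConfig(seed=3, n_sentences_general=80, n_sentences_target=40)
    return generate_domain_pair(cfg)


@pytest.fixture(scope="session")
def tiny_target(tiny_pair):
    return tiny_pair[1]


@pytest.fixture(scope="session")
def tiny_vocab(tiny_target):
    return build_vocabulary([tiny_target])


@pytest.fixture
def tiny_model_config():
    """2-unit layers in float64: small enough for finite differences."""
    return ModelConfig(
        word_embedding_dim=3,
        char_embedding_dim=2,
        char_hidden=2,
        layer_hidden=2,
        dropout_rate=0.0,
        dtype="float64",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
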