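import numpy as np
import pytest

from stslens import (
    CorpusConfig,
    ModelSpec,
    SentencePair,
    generate_corpus,
)


@pytest.fixture(scope="session")
def small_corpus():
    """120 train / 80 test pairs, default coupling; shared across tests."""
    return generate_corpus(CorpusConfig(n_train=120, n_test=80), seed=42)


@pytest.fixture(scope="session")
def tiny_model_spec():
    return ModelSpec(name="tiny12", n_layers=12, hidden_dim=16, layout="cls_first")


@pytest.fixture()
def hand_pair():
    """The worked frequency-feature example: A=[pain, pain], B=[pain]."""
    return SentencePair(
        pair_id="hand", tokens_a=("pain", "pain"), tokens_b=("pain",), score=5.0
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
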