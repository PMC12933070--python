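import pytest

from codonlm import (
    ModelConfig,
    SyntheticGenomeSpec,
    default_fixture_spec,
    deterministic_codon_model,
    generate_corpus,
    split_corpus,
    train,
)


@pytest.fixture(scope="session")
def fixture_spec():
    """The standard order-1 training fixture (2,000 pairs, seed 7)."""
    return default_fixture_spec(seed=7)


@pytest.fixture(scope="session")
def fixture_corpus(fixture_spec):
    return generate_corpus(fixture_spec)


@pytest.fixture(scope="session")
def fixture_split(fixture_corpus):
    return split_corpus(fixture_corpus, seed=7)


@pytest.fixture(scope="session")
def fixture_model(fixture_split):
    """Codon language model trained to convergence on the order-1 fixture."""
    return train(ModelConfig(max_epochs=30, seed=7), fixture_split)


@pytest.fixture(scope="session")
def det_spec():
    """Small corpus with a deterministic aa→codon mapping (Bayes accuracy 1)."""
    return SyntheticGenomeSpec(
        n_sequences=200,
        min_length=10,
        max_length=30,
        codon_model=deterministic_codon_model(),
        seed=2,
    )


@pytest.fixture(scope="session")
def det_corpus(det_spec):
    return generate_corpus(det_spec)


@pytest.fixture(scope="session")
def det_split(det_corpus):
    return split_corpus(det_corpus, seed=2)


@pytest.fixture(scope="session")
def small_config():
    return ModelConfig(
        aa_embedding_dim=8,
        codon_embedding_dim=8,
        encoder_units=16,
        decoder_codon_dense_size=16,
        decoder_aa_dense_size=16,
        decoder_units=24,
        learning_rate=1e-2,
        batch_size=16,
        max_epochs=50,
        seed=2,
    )


@pytest.fixture(scope="session")
def det_model(small_config, det_split):
    """Small model that memorises the deterministic mapping."""
    return train(small_config, det_split)
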