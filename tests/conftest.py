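import pytest

from syndromedx.rulebase import load_rulebase
from syndromedx.synthetic import (
    GeneratorConfig,
    Lexicon,
    generate_records,
    split_dataset,
)


@pytest.fixture(scope="session")
def rb():
    return load_rulebase()


@pytest.fixture(scope="session")
def lexicon():
    return Lexicon.default()


@pytest.fixture(scope="session")
def small_records(rb, lexicon):
    """400 default-condition records for cheap structural tests."""
    cfg = GeneratorConfig(n_records=400, seed=3)
    return generate_records(cfg, rb, lexicon)


@pytest.fixture(scope="session")
def highsignal_split(rb):
    """Noise-free, high-signal train/test split (n=2000, 10 patterns).

    Disjoint element lexica and six tokens per element make the task
    near-separable; this is the recovery regime in which every
    classifier family is expected to work.
    """
    cfg = GeneratorConfig(
        n_records=2000, seed=7, noise_token_rate=0.0, tokens_per_element=6.0
    )
    lex = Lexicon.default(overlap=0.0)
    records = generate_records(cfg, rb, lex)
    return split_dataset(records, (4, 1), "pattern", seed=7)


@pytest.fixture(scope="session")
def highsignal_word_model(highsignal_split):
    """One shared word model over the high-signal training corpus."""
    from syndromedx.corpus import build_corpus
    from syndromedx.embeddings import train_word_model

    train, _ = highsignal_split
    return train_word_model(
        build_corpus(train, 1), dimension=64, window=5, min_count=2,
        seed=7, epochs=10,
    )
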