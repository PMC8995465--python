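import numpy as np
import pytest

from litscape.synthetic_data import GeneratorConfig, generate, make_paper_fixture
from litscape.text_prep import BowCorpus, Vocabulary, build_corpus


@pytest.fixture(scope="session")
def small_corpus_pair():
    """A 300-document synthetic corpus with its ground truth (seed 5)."""
    config = GeneratorConfig(
        K_true=4,
        V=120,
        D=300,
        doc_length_mean=60,
        seed=5,
    )
    return generate(config)


@pytest.fixture(scope="session")
def clean_corpus_pair():
    """A corpus with no flagged records, for recovery-style tests."""
    config = GeneratorConfig(
        K_true=5,
        V=200,
        D=400,
        doc_length_mean=80,
        alpha_true=0.1,
        beta_true=0.01,
        excluded_type_count=0,
        non_english_or_short_count=0,
        seed=42,
    )
    return generate(config)


@pytest.fixture(scope="session")
def clean_bow(clean_corpus_pair):
    records, _ = clean_corpus_pair
    return build_corpus(records, min_df=1)


@pytest.fixture(scope="session")
def paper_fixture():
    """The screening-accounting corpus (60,453 records), generated once."""
    return make_paper_fixture(seed=1)


@pytest.fixture
def micro_corpus():
    """2 documents x 2 tokens over a 3-word vocabulary: small enough to
    enumerate every topic-assignment vector exactly."""
    vocab = Vocabulary(terms=["a", "b", "c"], min_df=1, stopwords=frozenset())
    return BowCorpus(
        docs=[{0: 1, 1: 1}, {1: 1, 2: 1}], doc_ids=["d1", "d2"], vocab=vocab
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
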