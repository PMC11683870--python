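import numpy as np
import pytest

from molminer.fixtures import FixtureSpec, toy_corpus
from molminer.strings import TokenVocabulary, build_vocabulary, BREAK_TOKEN


@pytest.fixture(scope="session")
def corpus_small():
    """300 unique valid molecules; enough to exercise distributions."""
    return toy_corpus(FixtureSpec(seed=11, size=300))


@pytest.fixture(scope="session")
def vocab_small(corpus_small):
    return build_vocabulary(corpus_small)


@pytest.fixture(scope="session")
def tiny_vocab():
    """Minimal hand-picked vocabulary for policy unit tests."""
    return TokenVocabulary(("[C]", "[O]", "[N]", "[=C]", BREAK_TOKEN))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
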