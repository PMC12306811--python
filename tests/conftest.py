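import pytest
from hypothesis import settings

from litmine.backends import OracleBackend
from litmine.corpus_model import SyntheticConfig, generate_corpus

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_corpus():
    """Two reviews, three included studies each, a dozen distractors with
    moderate term overlap."""
    return generate_corpus(SyntheticConfig(
        n_reviews=2, included_per_review=3, distractors_per_review=12,
        overlap_rate=0.2, seed=7))


@pytest.fixture(scope="session")
def oracle(small_corpus):
    return OracleBackend(small_corpus)


@pytest.fixture(scope="session")
def no_overlap_corpus():
    """Distractors share no planted vocabulary with their review."""
    return generate_corpus(SyntheticConfig(
        n_reviews=3, included_per_review=4, distractors_per_review=15,
        overlap_rate=0.0, seed=11))
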