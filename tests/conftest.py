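import pytest

from smokesurg import nlp
from smokesurg.cohort import CohortConfig, generate_cohort
from smokesurg.corpus import CorpusConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """Modest labeled corpus shared by the NLP tests."""
    return generate_corpus(CorpusConfig(n_sentences=2500, noise_rate=0.05, seed=11))


@pytest.fixture(scope="session")
def trained_model(small_corpus):
    """(model, train split, held-out split) on the shared corpus."""
    train, test = nlp.split_corpus(small_corpus, test_fraction=0.1, seed=0)
    model = nlp.train_classifier(train, nlp.TrainConfig(seed=1))
    return model, train, test


@pytest.fixture(scope="session")
def demo_cohort():
    """Default-parameter cohort large enough for stable marginals."""
    return generate_cohort(CohortConfig(n_patients=8000, seed=5))
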