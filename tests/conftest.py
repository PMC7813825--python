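import numpy as np
import pytest

from locrex.embeddings import EmbeddingMatrix, build_vocab
from locrex.instances import PAD
from locrex.synthetic import GeneratorSpec, generate_corpus, make_classifier_dataset


@pytest.fixture(scope="session")
def small_corpus():
    """120 synthetic sentences over 12 papers — enough for every pipeline stage."""
    return generate_corpus(GeneratorSpec(n_sentences=120, sentences_per_paper=10, seed=11))


@pytest.fixture(scope="session")
def small_dataset(small_corpus):
    """Balanced 40+40 instance set from the small corpus."""
    return make_classifier_dataset(small_corpus, n_pairs=40, seed=7)


@pytest.fixture(scope="session")
def small_vocab(small_dataset):
    return build_vocab([[t for t in i.tokens if t != PAD] for i in small_dataset], min_count=1)


@pytest.fixture(scope="session")
def small_embeddings(small_vocab):
    """Random (not CBOW-trained) embeddings: classifier unit tests only need shapes."""
    rng = np.random.default_rng(3)
    weights = rng.normal(0, 0.1, size=(len(small_vocab), 16)).astype(np.float32)
    weights[small_vocab.token_to_index[PAD]] = 0.0
    return EmbeddingMatrix(weights=weights, vocab=small_vocab)
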