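import numpy as np
import pytest

import hatescan as hs


@pytest.fixture(scope="session")
def default_lexicon():
    return hs.build_lexicon(hs.default_gazetteer())


@pytest.fixture(scope="session")
def small_corpus():
    """Mixed corpus with duplicates, retweets and location noise."""
    cfg = hs.CorpusConfig(n_tweets=400, seed=3)
    return hs.generate_corpus(cfg)


@pytest.fixture(scope="session")
def noise_free_corpus():
    cfg = hs.CorpusConfig(n_tweets=400, alias_noise_rate=0.0,
                          unlocated_rate=0.0, seed=5)
    return hs.generate_corpus(cfg)


@pytest.fixture(scope="session")
def separable_training():
    """Fully separable labeled set with an 80/20 train/test split."""
    df = hs.generate_labeled_training_set(2000, 1.0, seed=11)
    texts = [hs.preprocess_text(t, "classifier").tokens for t in df.text]
    labels = df.label.to_numpy()
    train_mask = np.arange(len(df)) % 5 != 0
    return texts, labels, train_mask


@pytest.fixture(scope="session")
def small_cnn_config():
    return hs.CNNConfig(epochs=3, seed=1, embed_dim=50,
                        filters_per_kernel=50, max_len=30)


@pytest.fixture(scope="session")
def trained_cnn(separable_training, small_cnn_config):
    texts, labels, train_mask = separable_training
    train_texts = [t for t, m in zip(texts, train_mask) if m]
    return hs.train(small_cnn_config, train_texts, labels[train_mask].tolist())
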