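"""TF-IDF features and NMF topic extraction contracts."""
import numpy as np
import pytest

import hatescan as hs
from hatescan.topics import UNASSIGNED, umass_coherence


def _topic_docs(n_docs=800, n_topics=7, seed=13):
    cfg = hs.CorpusConfig(n_tweets=n_docs, hate_prevalence=1.0,
                          duplicate_rate=0.0, retweet_rate=0.0,
                          n_topics_planted=n_topics, seed=seed)
    corpus = hs.generate_corpus(cfg)
    docs = [hs.preprocess_text(r.text, "topic",
                               stopwords=hs.DEFAULT_STOPWORDS).tokens
            for r in corpus.records]
    return corpus, docs


# -- TF-IDF --------------------------------------------------------------


def test_tfidf_single_token_document():
    dtm = hs.build_tfidf([["كلمه"]], min_df=1)
    assert dtm.shape == (1, 1)
    assert dtm.X[0, 0] > 0


def test_tfidf_rarer_term_has_larger_idf():
    docs = [["عام", "نادر"], ["عام"], ["عام"]]
    dtm = hs.build_tfidf(docs, min_df=1)
    common = dtm.vocabulary.index("عام")
    rare = dtm.vocabulary.index("نادر")
    # same raw count in doc 0, so the tf-idf entry ranks by idf alone
    assert dtm.X[0, rare] > dtm.X[0, common]


def test_tfidf_matches_hand_computation():
    docs = [["ا", "ب"], ["ا"], ["ا", "ج"]]
    dtm = hs.build_tfidf(docs, min_df=1)
    vocab = dtm.vocabulary
    # unigrams + adjacent bigrams
    assert set(vocab) == {"ا", "ب", "ج", "ا ب", "ا ج"}
    n = 3
    df = {"ا": 3, "ب": 1, "ج": 1, "ا ب": 1, "ا ج": 1}
    idf = {t: np.log((1 + n) / (1 + d)) + 1 for t, d in df.items()}
    for i, doc in enumerate(docs):
        terms = list(doc) + [" ".join(p) for p in zip(doc, doc[1:])]
        raw = np.array([terms.count(t) * idf[t] for t in vocab])
        expected = raw / np.linalg.norm(raw)
        np.testing.assert_allclose(dtm.X[i].toarray().ravel(), expected,
                                   atol=1e-12)


def test_tfidf_empty_document_set_rejected():
    with pytest.raises(ValueError):
        hs.build_tfidf([])


# -- NMF fitting ---------------------------------------------------------


def test_rank_one_matrix_factors_exactly():
    u = np.array([[1.0], [2.0], [4.0]])
    v = np.array([[3.0, 1.0, 0.5, 2.0]])
    import scipy.sparse as sp
    dtm = hs.DocTermMatrix(sp.csr_matrix(u @ v), [f"t{i}" for i in range(4)])
    model = hs.fit_nmf(dtm, k=1, max_iter=500, tol=0)
    assert model.objective_trace[-1] <= 1e-8


def test_objective_trace_monotone_on_random_matrix():
    rng = np.random.default_rng(4)
    import scipy.sparse as sp
    X = sp.csr_matrix(rng.random((20, 30)))
    dtm = hs.DocTermMatrix(X, [f"t{i}" for i in range(30)])
    model = hs.fit_nmf(dtm, k=5, max_iter=100, tol=0)
    tr = model.objective_trace
    assert all(a >= b - 1e-9 for a, b in zip(tr, tr[1:]))
    assert np.all(model.W >= 0) and np.all(model.H >= 0)


def test_nmf_reconstruction_comparable_to_sklearn():
    """Independent cross-check: the multiplicative-update fit should reach a
    reconstruction error in the same range as sklearn's coordinate-descent
    NMF on the same matrix."""
    from sklearn.decomposition import NMF
    rng = np.random.default_rng(7)
    import scipy.sparse as sp
    X = sp.csr_matrix(rng.random((40, 60)))
    dtm = hs.DocTermMatrix(X, [f"t{i}" for i in range(60)])
    mine = hs.fit_nmf(dtm, k=5, max_iter=500, tol=1e-8)
    ref = NMF(n_components=5, init="nndsvda", max_iter=1000, tol=1e-8,
              random_state=0).fit(X)
    ref_err = np.linalg.norm(X.toarray()
                             - ref.transform(X) @ ref.components_)
    assert mine.objective_trace[-1] <= ref_err * 1.05


def test_nmf_bad_inputs_rejected():
    import scipy.sparse as sp
    dtm = hs.DocTermMatrix(sp.csr_matrix(np.ones((3, 4))), list("abcd"))
    with pytest.raises(ValueError):
        hs.fit_nmf(dtm, k=0)
    with pytest.raises(ValueError):
        hs.fit_nmf(dtm, k=5)
    neg = hs.DocTermMatrix(sp.csr_matrix(np.array([[1.0, -1.0]])), list("ab"))
    with pytest.raises(ValueError, match="nonnegative"):
        hs.fit_nmf(neg, k=1)


def test_planted_anchor_topics_recovered():
    corpus, docs = _topic_docs(n_docs=800, n_topics=5, seed=17)
    model = hs.fit_nmf(hs.build_tfidf(docs), k=5)
    tops = hs.top_terms(model, 10)
    remaining = set(range(5))
    for anchors in corpus.anchors:
        match = next((t for t in remaining
                      if all(a in tops[t] for a in anchors)), None)
        assert match is not None, f"anchors {anchors} not recovered"
        remaining.discard(match)
    # disjoint planted anchors give disjoint top-3 lists across topics
    top3 = [set(t[:3]) for t in tops]
    for i in range(len(top3)):
        for j in range(i):
            assert not top3[i] & top3[j]


# -- topic summaries -----------------------------------------------------


def test_top_terms_match_brute_force_sort():
    H = np.array([[0.5, 0.1, 0.5, 0.9], [0.0, 0.2, 0.2, 0.1]])
    model = hs.TopicModel(W=np.zeros((1, 2)), H=H, k=2,
                          vocabulary=["ب", "ج", "ا", "د"],
                          objective_trace=[0.0])
    assert hs.top_terms(model, 1) == [["د"], ["ا"]]  # tie "ا"/"ج" -> lexicographic
    brute = [[t for _, t in sorted(zip(-H[i], model.vocabulary))][:3]
             for i in range(2)]
    # note: plain sorted() on (-weight, term) pairs is the brute-force rank
    assert hs.top_terms(model, 3) == brute


def test_topic_distribution_single_topic_and_zero_rows():
    W = np.array([[0.5], [0.2], [0.0]])
    model = hs.TopicModel(W=W, H=np.ones((1, 2)), k=1,
                          vocabulary=["ا", "ب"], objective_trace=[0.0])
    dist = hs.topic_distribution(model)
    assert dist[0] == pytest.approx(200 / 3)
    assert dist[UNASSIGNED] == pytest.approx(100 / 3)
    assert dist.sum() == pytest.approx(100.0, abs=0.1)


def test_planted_mixture_proportions_recovered():
    cfg = hs.CorpusConfig(n_tweets=1500, hate_prevalence=1.0,
                          duplicate_rate=0.0, retweet_rate=0.0,
                          n_topics_planted=3, topic_weights=(0.6, 0.2, 0.2),
                          seed=21)
    corpus = hs.generate_corpus(cfg)
    docs = [hs.preprocess_text(r.text, "topic",
                               stopwords=hs.DEFAULT_STOPWORDS).tokens
            for r in corpus.records]
    model = hs.fit_nmf(hs.build_tfidf(docs), k=3)
    shares = sorted(hs.topic_distribution(model).values, reverse=True)
    for got, want in zip(shares, (60.0, 20.0, 20.0)):
        assert abs(got - want) <= 5.0


def test_umass_coherence_diagnostic_orders_topics():
    docs = [["ا", "ب"]] * 20 + [["ج", "د"]] * 20 + [["ا", "د"]]
    coherent = umass_coherence([["ا", "ب"]], docs)[0]
    incoherent = umass_coherence([["ا", "ج"]], docs)[0]
    assert coherent > incoherent
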