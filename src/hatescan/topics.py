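"""Topic extraction from hate tweets: TF-IDF features + nonnegative matrix
factorization.

Documents (tweets preprocessed in topic mode) become rows of a TF-IDF matrix
over unigrams and adjacent bigrams (raw term counts, smoothed logarithmic
idf, L2-normalized rows, minimum document frequency 2).  The matrix is
factored as X ≈ WH with W, H ≥ 0 by multiplicative updates from a
deterministic SVD-based nonnegative initialization, so a fitted model is
reproducible without seed sweeps.  Topics are summarized by their
highest-weight terms and by the share of documents whose W row peaks on
them.

The default topic count is 7, matching the study configuration this
pipeline reimplements; it is a plain parameter.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from sklearn.feature_extraction.text import TfidfVectorizer

__all__ = [
    "DocTermMatrix",
    "TopicModel",
    "build_tfidf",
    "fit_nmf",
    "top_terms",
    "topic_distribution",
    "umass_coherence",
]

UNASSIGNED = "unassigned"


@dataclass
class DocTermMatrix:
    """Nonnegative documents × terms matrix with its vocabulary."""

    X: sp.csr_matrix
    vocabulary: list[str]
    params: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


def _uni_bigrams(tokens: Sequence[str]) -> list[str]:
    terms = list(tokens)
    terms.extend(f"{a} {b}" for a, b in zip(tokens, tokens[1:]))
    return terms


def build_tfidf(documents: Sequence[Sequence[str]], min_df: int = 2) -> DocTermMatrix:
    """TF-IDF matrix over unigrams + adjacent bigrams of tokenized docs.

    Raw term counts, smoothed idf ``ln((1+n)/(1+df)) + 1``, rows
    L2-normalized; terms below ``min_df`` documents are dropped.
    """
    if len(documents) == 0:
        raise ValueError("cannot build TF-IDF from an empty document set")
    vec = TfidfVectorizer(
        analyzer=_uni_bigrams,
        min_df=min_df,
        norm="l2",
        smooth_idf=True,
        sublinear_tf=False,
    )
    X = vec.fit_transform(documents)
    vocab = vec.get_feature_names_out().tolist()
    params = {"ngrams": "unigrams+adjacent bigrams", "min_df": min_df,
              "tf": "raw count", "idf": "smooth log", "norm": "l2"}
    return DocTermMatrix(sp.csr_matrix(X), vocab, params)


@dataclass
class TopicModel:
    """Nonnegative factor pair W (docs × k), H (k × terms)."""

    W: np.ndarray
    H: np.ndarray
    k: int
    vocabulary: list[str]
    objective_trace: list[float]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.W).to_csv(directory / "W.csv", index=False)
        pd.DataFrame(self.H, columns=self.vocabulary).to_csv(
            directory / "H.csv", index=False)


def _nndsvda_init(X: sp.csr_matrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic nonnegative double-SVD initialization (zeros filled
    with the matrix mean)."""
    n, m = X.shape
    if k < min(n, m):
        U, S, Vt = svds(X.astype(np.float64), k=k, v0=np.ones(min(n, m)))
        order = np.argsort(-S)
        U, S, Vt = U[:, order], S[order], Vt[order]
    else:
        U, S, Vt = np.linalg.svd(np.asarray(X.todense(), dtype=np.float64),
                                 full_matrices=False)
        U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # fix SVD sign ambiguity: dominant entry of each left vector positive
    for j in range(k):
        if U[np.argmax(np.abs(U[:, j])), j] < 0:
            U[:, j] = -U[:, j]
            Vt[j] = -Vt[j]
    W = np.zeros((n, k))
    H = np.zeros((k, m))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for j in range(1, k):
        u, v = U[:, j], Vt[j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        norm_p = np.linalg.norm(up) * np.linalg.norm(vp)
        norm_n = np.linalg.norm(un) * np.linalg.norm(vn)
        if norm_p >= norm_n and norm_p > 0:
            W[:, j] = np.sqrt(S[j] * norm_p) * up / np.linalg.norm(up)
            H[j] = np.sqrt(S[j] * norm_p) * vp / np.linalg.norm(vp)
        elif norm_n > 0:
            W[:, j] = np.sqrt(S[j] * norm_n) * un / np.linalg.norm(un)
            H[j] = np.sqrt(S[j] * norm_n) * vn / np.linalg.norm(vn)
    mean = X.mean()
    W[W == 0] = mean
    H[H == 0] = mean
    return W, H


def _frobenius_error(X: sp.csr_matrix, W: np.ndarray, H: np.ndarray,
                     normX2: float) -> float:
    cross = float(np.sum((W.T @ X) * H))
    gram = float(np.trace((W.T @ W) @ (H @ H.T)))
    return float(np.sqrt(max(normX2 - 2.0 * cross + gram, 0.0)))


def fit_nmf(
    dtm: DocTermMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> TopicModel:
    """Factor the TF-IDF matrix by Frobenius multiplicative updates.

    Initialization is the deterministic SVD-based scheme, so the result does
    not depend on ``seed`` (the parameter is accepted for interface
    stability).  The recorded objective trace ‖X − WH‖_F is non-increasing
    up to floating-point tolerance — a guarantee of the multiplicative
    update rule.  Stops at ``max_iter`` or when the relative objective
    change falls below ``tol``.
    """
    X = dtm.X
    n, m = X.shape
    if k < 1 or k > min(n, m):
        raise ValueError(f"k must lie in [1, {min(n, m)}], got {k}")
    if X.nnz and X.data.min() < 0:
        raise ValueError("input matrix must be nonnegative")
    eps = 1e-10
    W, H = _nndsvda_init(X, k)
    normX2 = float(X.multiply(X).sum())
    trace = [_frobenius_error(X, W, H, normX2)]
    for _ in range(max_iter):
        WtX = np.asarray(W.T @ X)
        H *= WtX / (W.T @ W @ H + eps)
        XHt = np.asarray(X @ H.T)
        W *= XHt / (W @ (H @ H.T) + eps)
        trace.append(_frobenius_error(X, W, H, normX2))
        if trace[-2] > 0 and abs(trace[-2] - trace[-1]) / trace[-2] < tol:
            break
    return TopicModel(W=W, H=H, k=k, vocabulary=list(dtm.vocabulary),
                      objective_trace=trace)


def top_terms(model: TopicModel, n: int = 10) -> list[list[str]]:
    """The ``n`` highest-weight terms per topic (ties lexicographic)."""
    out = []
    vocab = model.vocabulary
    for row in model.H:
        ranked = sorted(zip(row, vocab), key=lambda wt: (-wt[0], wt[1]))
        out.append([term for _, term in ranked[:n]])
    return out


def topic_distribution(model: TopicModel) -> pd.Series:
    """Share of documents (%) assigned to each topic by W-row argmax.

    Ties go to the lowest topic index; documents with an all-zero W row are
    reported under a separate ``unassigned`` bucket.
    """
    n_docs = model.W.shape[0]
    if n_docs == 0:
        raise ValueError("model was fitted on zero documents")
    counts: dict[object, int] = {t: 0 for t in range(model.k)}
    zero_rows = 0
    assignments = model.W.argmax(axis=1)
    for row, topic in zip(model.W, assignments):
        if np.all(row == 0):
            zero_rows += 1
        else:
            counts[int(topic)] += 1
    shares = {t: c / n_docs * 100.0 for t, c in counts.items()}
    if zero_rows:
        shares[UNASSIGNED] = zero_rows / n_docs * 100.0
    return pd.Series(shares)


def umass_coherence(
    topic_terms: Sequence[Sequence[str]],
    documents: Sequence[Sequence[str]],
) -> list[float]:
    """Optional diagnostic (an extension beyond the core pipeline): UMass
    topic coherence, Σ log (D(w_i, w_j) + 1) / D(w_j) over ranked term pairs.

    More coherent topics give values closer to 0.
    """
    doc_sets = [set(_uni_bigrams(list(d))) for d in documents]
    out = []
    for terms in topic_terms:
        score = 0.0
        for i in range(1, len(terms)):
            for j in range(i):
                d_j = sum(terms[j] in ds for ds in doc_sets)
                if d_j == 0:
                    continue
                d_ij = sum(terms[i] in ds and terms[j] in ds for ds in doc_sets)
                score += np.log((d_ij + 1) / d_j)
        out.append(float(score))
    return out
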