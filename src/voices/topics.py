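"""TF-IDF weighting, NMF topic models, TC-W2V coherence, selection of k.

The document-term matrix uses raw term frequency times an unsmoothed
inverse document frequency, idf(t) = ln(N / df(t)). Under this convention
a term present in every document gets weight exactly zero — ubiquitous
words cannot influence the factorisation — and is pruned from the
vocabulary along with stop words and terms below ``min_df``.

Topics come from non-negative matrix factorisation (Frobenius objective,
deterministic SVD-based initialisation), read off as the highest-weight
terms per topic. Model order k is chosen by TC-W2V coherence: the mean
pairwise cosine similarity, under corpus-trained word embeddings, of each
topic's top terms, averaged over topics; k* maximises the mean coherence,
with ties broken toward the smaller (more parsimonious) k and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import NMF

from voices.corpus import DocumentSet
from voices.embeddings import EmbeddingMap, EmbeddingParams, train_embeddings

DEFAULT_TOP_WORDS = 10


@dataclass
class TermWeightMatrix:
    vocabulary: list            # ordered term list
    matrix: np.ndarray          # documents x terms, tf-idf weights >= 0
    doc_ids: list


@dataclass
class TopicModelResult:
    k: int
    W: np.ndarray               # documents x k
    H: np.ndarray               # k x terms
    top_words: list             # per topic: [(term, weight)] best-first
    seed: int
    reconstruction_error: float
    coherence_per_topic: list = field(default_factory=list)
    mean_coherence: float = math.nan


@dataclass
class SelectKResult:
    k_star: int
    results: dict               # k -> TopicModelResult
    tie: bool = False
    errors: dict = field(default_factory=dict)


def build_tfidf(document_set: DocumentSet, min_df: int = 2,
                stopword_policy: str = "exclude") -> TermWeightMatrix:
    """Build the documents × terms TF-IDF matrix.

    weight(d, t) = tf(d, t) · ln(N / df(t)). Stop words are excluded from
    the vocabulary under the default policy; terms with df < ``min_df`` or
    df = N (idf 0) are pruned.
    """
    docs = document_set.documents
    if len(docs) < 2:
        raise ValueError("TF-IDF needs at least 2 documents")
    if stopword_policy not in ("exclude", "keep"):
        raise ValueError(f"unknown stopword_policy: {stopword_policy!r}")

    token_lists = [
        doc.content_tokens() if stopword_policy == "exclude" else list(doc.tokens)
        for doc in docs
    ]
    n = len(docs)
    df: dict[str, int] = {}
    for tokens in token_lists:
        for term in set(tokens):
            df[term] = df.get(term, 0) + 1
    vocab = sorted(t for t, d in df.items() if min_df <= d < n)
    if not vocab:
        raise ValueError("empty vocabulary after stop-word/df filtering")
    index = {t: i for i, t in enumerate(vocab)}

    matrix = np.zeros((n, len(vocab)))
    for row, tokens in enumerate(token_lists):
        for term in tokens:
            col = index.get(term)
            if col is not None:
                matrix[row, col] += 1.0
    idf = np.array([math.log(n / df[t]) for t in vocab])
    matrix *= idf
    doc_ids = [f"{d.respondent_id}/{d.question_id}" for d in docs]
    return TermWeightMatrix(vocab, matrix, doc_ids)


def fit_nmf(matrix: TermWeightMatrix, k: int, seed: int = 0,
            max_iter: int = 500, tol: float = 1e-5,
            n_top_words: int = DEFAULT_TOP_WORDS) -> TopicModelResult:
    """Factorise the TF-IDF matrix into k non-negative topics.

    Uses the Frobenius objective with deterministic non-negative double-SVD
    initialisation, so a fixed (matrix, k, seed) gives identical factors.
    """
    n_docs, n_terms = matrix.matrix.shape
    if not (1 <= k <= min(n_docs, n_terms)):
        raise ValueError(
            f"k = {k} outside [1, {min(n_docs, n_terms)}] for a "
            f"{n_docs} x {n_terms} matrix")
    init = "nndsvd" if k > 1 else "nndsvda"
    model = NMF(n_components=k, init=init, max_iter=max_iter, tol=tol,
                random_state=seed)
    w = model.fit_transform(matrix.matrix)
    h = model.components_
    top_words = []
    for row in h:
        order = np.argsort(-row, kind="stable")[:n_top_words]
        top_words.append([(matrix.vocabulary[i], float(row[i])) for i in order])
    return TopicModelResult(k, w, h, top_words, seed,
                            float(model.reconstruction_err_))


def tcw2v_coherence(topic_top_words, embeddings: EmbeddingMap) -> float:
    """Mean pairwise cosine similarity of a topic's top words; in [−1, 1].

    ``topic_top_words`` is a list of terms or (term, weight) pairs. A term
    without an embedding raises a KeyError naming it.
    """
    terms = [t[0] if isinstance(t, (tuple, list)) else t
             for t in topic_top_words]
    if len(terms) < 2:
        raise ValueError("coherence needs at least 2 top words")
    for term in terms:
        if term not in embeddings:
            raise KeyError(f"no embedding for term {term!r}")
    sims = [embeddings.cosine(a, b)
            for i, a in enumerate(terms) for b in terms[i + 1:]]
    return float(np.mean(sims))


def score_model(result: TopicModelResult, embeddings: EmbeddingMap
                ) -> TopicModelResult:
    """Fill per-topic and mean TC-W2V coherence on a fitted model."""
    result.coherence_per_topic = [
        tcw2v_coherence(words, embeddings) for words in result.top_words
    ]
    result.mean_coherence = float(np.mean(result.coherence_per_topic))
    return result


def select_k(matrix: TermWeightMatrix, k_range, embeddings: EmbeddingMap,
             seed: int = 0, n_top_words: int = DEFAULT_TOP_WORDS
             ) -> SelectKResult:
    """Fit NMF for each k and pick the coherence-maximising model order.

    k* = argmax of mean TC-W2V coherence; an exact tie goes to the smaller
    k and sets the tie flag. Per-k fit errors are collected; if no k fits,
    the first error is re-raised.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    results: dict[int, TopicModelResult] = {}
    errors: dict[int, Exception] = {}
    for k in ks:
        try:
            results[k] = score_model(
                fit_nmf(matrix, k, seed=seed, n_top_words=n_top_words),
                embeddings)
        except (ValueError, KeyError) as exc:
            errors[k] = exc
    if not results:
        raise next(iter(errors.values()))
    scores = {k: (r.mean_coherence if math.isfinite(r.mean_coherence)
                  else -math.inf) for k, r in results.items()}
    best = max(scores.values())
    if best == -math.inf:
        raise ValueError("coherence undefined for every k")
    tied = [k for k, s in scores.items() if s == best]
    return SelectKResult(k_star=min(tied), results=results,
                         tie=len(tied) > 1, errors=errors)


def embeddings_for(document_set: DocumentSet, seed: int = 0,
                   params: EmbeddingParams | None = None) -> EmbeddingMap:
    """Train corpus embeddings with the module defaults and the given seed."""
    params = params or EmbeddingParams()
    params.seed = seed
    return train_embeddings(document_set, params)
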