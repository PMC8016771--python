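"""Skip-gram word embeddings trained on the analysis corpus.

TC-W2V topic coherence needs a vector per vocabulary term, trained on the
corpus being modelled. This is a compact, fully vectorised implementation
of skip-gram with negative sampling (SGNS): for each (centre, context)
pair within a symmetric window, the centre vector is pushed towards the
context's output vector and away from ``negative`` sampled noise words
drawn from the unigram distribution raised to 3/4. Training is
single-threaded and seeded, so identical inputs give identical vectors.

Defaults (dimension 100, window 5, min_count 1, 50 epochs) suit the small
corpora this pipeline sees: min_count 1 guarantees every modelled term has
a vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EmbeddingParams:
    dim: int = 100
    window: int = 5
    min_count: int = 1
    epochs: int = 50
    negative: int = 5
    learning_rate: float = 0.025
    subsample: float = 5e-3    # frequent-word downsampling threshold
    batch_size: int = 1024
    seed: int = 0


@dataclass
class EmbeddingMap:
    """Term -> vector mapping with the training parameters that made it."""

    vectors: dict            # term -> np.ndarray (all same dimension)
    params: EmbeddingParams = field(default_factory=EmbeddingParams)

    def __contains__(self, term: str) -> bool:
        return term in self.vectors

    def __getitem__(self, term: str) -> np.ndarray:
        if term not in self.vectors:
            raise KeyError(f"no embedding for term {term!r}")
        return self.vectors[term]

    def cosine(self, a: str, b: str) -> float:
        u, v = self[a], self[b]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0.0 or nv == 0.0:
            return 0.0
        return float(np.dot(u, v) / (nu * nv))


def _sentences(document_set) -> list[list[str]]:
    out = []
    for doc in document_set.documents:
        tokens = doc.content_tokens() if doc.stopword_mask else doc.tokens
        if tokens:
            out.append(tokens)
    return out


def _skipgram_pairs(encoded: list[np.ndarray], window: int,
                    rng: np.random.Generator) -> np.ndarray:
    """(centre, context) pairs with per-position dynamic window sampling.

    As in word2vec, the effective window at each position is drawn uniformly
    from 1..window, which both weights nearby contexts higher and keeps the
    pair count manageable.
    """
    pairs = []
    for sent in encoded:
        n = sent.size
        if n < 2:
            continue
        widths = rng.integers(1, window + 1, size=n)
        for offset in range(1, window + 1):
            if n <= offset:
                break
            keep_l = widths[offset:] >= offset      # centre = right position
            keep_r = widths[:-offset] >= offset     # centre = left position
            left = sent[:-offset]
            right = sent[offset:]
            pairs.append(np.stack([right[keep_l], left[keep_l]], axis=1))
            pairs.append(np.stack([left[keep_r], right[keep_r]], axis=1))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(pairs, axis=0)


def train_embeddings(document_set, params: EmbeddingParams | None = None
                     ) -> EmbeddingMap:
    """Train SGNS embeddings on a prepared document set.

    Stop-word-masked tokens are left out of training (coherence is computed
    over content terms only). Deterministic for a fixed seed.
    """
    params = params or EmbeddingParams()
    sentences = _sentences(document_set)
    if not sentences:
        raise ValueError("cannot train embeddings on an empty corpus")

    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= params.min_count)
    index = {t: i for i, t in enumerate(vocab)}
    v = len(vocab)
    if v == 0:
        raise ValueError("no term reaches min_count")

    rng = np.random.default_rng(np.random.SeedSequence(params.seed))

    # frequent-word subsampling: keep token w with prob min(1, sqrt(t/f(w)))
    n_tokens = sum(counts[t] for t in vocab)
    keep_prob = np.ones(v)
    if params.subsample > 0:
        freq = np.array([counts[t] for t in vocab], dtype=float) / n_tokens
        keep_prob = np.minimum(1.0, np.sqrt(params.subsample / freq))

    encoded = []
    for sent in sentences:
        ids = np.array([index[t] for t in sent if t in index], dtype=np.int64)
        if ids.size:
            ids = ids[rng.random(ids.size) < keep_prob[ids]]
        if ids.size:
            encoded.append(ids)
    pairs = _skipgram_pairs(encoded, params.window, rng)

    w_in = (rng.random((v, params.dim)) - 0.5) / params.dim
    w_out = np.zeros((v, params.dim))
    if pairs.shape[0] == 0:
        vectors = {t: w_in[i].copy() for t, i in index.items()}
        return EmbeddingMap(vectors, params)

    freq = np.array([counts[t] for t in vocab], dtype=float) ** 0.75
    noise = freq / freq.sum()

    n_pairs = pairs.shape[0]
    batches_per_epoch = max(1, int(np.ceil(n_pairs / params.batch_size)))
    total_batches = params.epochs * batches_per_epoch
    batch_no = 0
    for _ in range(params.epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, params.batch_size):
            lr = params.learning_rate * max(
                1e-4, 1.0 - batch_no / total_batches)
            batch = pairs[order[start:start + params.batch_size]]
            centres, contexts = batch[:, 0], batch[:, 1]
            negs = rng.choice(v, size=(batch.shape[0], params.negative),
                              p=noise)

            c_vec = w_in[centres]                       # (B, D)
            targets = np.concatenate(
                [contexts[:, None], negs], axis=1)      # (B, 1+K)
            t_vec = w_out[targets]                      # (B, 1+K, D)
            score = np.einsum("bd,bkd->bk", c_vec, t_vec)
            sig = 1.0 / (1.0 + np.exp(-np.clip(score, -10, 10)))
            label = np.zeros_like(sig)
            label[:, 0] = 1.0
            g = (label - sig) * lr                      # (B, 1+K)

            grad_c = np.einsum("bk,bkd->bd", g, t_vec)
            grad_t = g[:, :, None] * c_vec[:, None, :]
            np.add.at(w_in, centres, grad_c)
            np.add.at(w_out, targets.ravel(),
                      grad_t.reshape(-1, params.dim))
            batch_no += 1

    vectors = {t: w_in[i].copy() for t, i in index.items()}
    return EmbeddingMap(vectors, params)
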