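"""Distinctive-phrase extraction per disease group via the KLIP metric.

For each group's pooled open-text answers (the foreground), candidate
phrases are all 1–4-token n-grams that occur entirely inside a single
response, do not start or end with a stop word, and occur at least twice.
Three- and four-word candidates repeated by the same respondent are counted
once, so a single insistent respondent cannot dominate a group's ranking.

Each candidate gets two pointwise KL-divergence scores (natural log):

* informativeness  I = P_fg(w) · ln(P_fg(w) / P_bg(w)) — how much more
  probable the phrase is in the group's answers than in a generic
  background corpus;
* phraseness       P = P_fg(w) · ln(P_fg(w) / ∏ᵢ P_fg(wᵢ)) — how much more
  probable the phrase is than its words would be independently
  (exactly 0 for single words).

The combined score is klip = γ·I + (1−γ)·P with γ = 0.8 by default, i.e.
informativeness-dominant; the orientation is switchable. Probabilities are
per-n-gram-length relative frequencies; the background model is add-one
smoothed over the union vocabulary of foreground and background n-grams of
that length, so phrases unseen in the background get a finite floor rather
than an infinite score.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from voices.corpus import Document, tokenize_lemmatize

MAX_PHRASE_LEN = 4
MIN_FG_COUNT = 2
DEFAULT_GAMMA = 0.8


def iter_ngrams(tokens: Sequence[str], max_len: int = MAX_PHRASE_LEN):
    """All within-sequence n-grams up to max_len, as (start, tuple)."""
    n = len(tokens)
    for start in range(n):
        for length in range(1, min(max_len, n - start) + 1):
            yield start, tuple(tokens[start:start + length])


@dataclass
class BackgroundCorpus:
    """n-gram count tables (lengths 1–4) over a background text collection."""

    counts: dict            # length -> Counter of n-gram tuples
    totals: dict            # length -> total occurrences of that length
    total_tokens: int

    @classmethod
    def from_lines(cls, lines: Iterable[str]) -> "BackgroundCorpus":
        """Count n-grams in a one-document-per-line corpus.

        Lines get the same normalisation as survey answers (lowercasing,
        punctuation stripping, lemmatisation); n-grams never span lines.
        """
        counts = {n: Counter() for n in range(1, MAX_PHRASE_LEN + 1)}
        totals = {n: 0 for n in range(1, MAX_PHRASE_LEN + 1)}
        total_tokens = 0
        for line in lines:
            tokens, _ = tokenize_lemmatize(line)
            total_tokens += len(tokens)
            for _, gram in iter_ngrams(tokens):
                counts[len(gram)][gram] += 1
                totals[len(gram)] += 1
        return cls(counts, totals, total_tokens)

    @classmethod
    def from_file(cls, path) -> "BackgroundCorpus":
        with open(path, encoding="utf-8") as fh:
            return cls.from_lines(fh)


@dataclass
class CandidatePhrase:
    lemmas: tuple
    fg_count: int
    doc_ids: set = field(default_factory=set)
    respondent_ids: set = field(default_factory=set)
    occurrences: list = field(default_factory=list)  # (doc index, respondent)

    @property
    def length(self) -> int:
        return len(self.lemmas)


@dataclass
class PhraseScore:
    phrase: tuple
    fg_count: int
    phraseness: float
    informativeness: float
    klip: float
    gamma: float

    @property
    def text(self) -> str:
        return " ".join(self.phrase)


class LanguageModel:
    """Add-α n-gram probability: P(w) = (count(w) + α) / (total + α·V)."""

    def __init__(self, counts, total: int, alpha: float = 0.0,
                 vocab_size: int = 0):
        if alpha > 0 and vocab_size <= 0:
            raise ValueError("smoothing needs a positive vocabulary size")
        if total + alpha * vocab_size <= 0:
            raise ValueError("language model needs positive probability mass")
        self.counts = counts
        self.total = total
        self.alpha = alpha
        self.vocab_size = vocab_size

    def prob(self, phrase: tuple) -> float:
        count = self.counts.get(phrase, 0)
        return (count + self.alpha) / (self.total + self.alpha * self.vocab_size)


def extract_candidates(mtg_documents: Sequence[Document]
                       ) -> list[CandidatePhrase]:
    """Enumerate candidate phrases over one group's documents.

    Documents must carry tokens and stop-word masks. Candidates are 1–4
    grams that lie within a single response, have non-stop-word first and
    last tokens, and occur at least twice across the group (before
    per-respondent de-duplication).
    """
    occurrences: dict[tuple, list] = {}
    for doc_index, doc in enumerate(mtg_documents):
        mask = doc.stopword_mask
        for start, gram in iter_ngrams(doc.tokens):
            end = start + len(gram) - 1
            if mask[start] or mask[end]:
                continue
            occurrences.setdefault(gram, []).append(
                (doc_index, doc.respondent_id))
    out = []
    for gram in sorted(occurrences):
        occ = occurrences[gram]
        if len(occ) < MIN_FG_COUNT:
            continue
        out.append(CandidatePhrase(
            lemmas=gram, fg_count=len(occ),
            doc_ids={i for i, _ in occ},
            respondent_ids={r for _, r in occ},
            occurrences=occ,
        ))
    return out


def dedup_per_respondent(candidates: Iterable[CandidatePhrase]
                         ) -> list[CandidatePhrase]:
    """Collapse repeated 3–4-gram occurrences by the same respondent to one.

    One- and two-word candidates keep their raw occurrence counts; the rule
    targets longer combinations only, where repetition by one person would
    bias the group ranking.
    """
    out = []
    for cand in candidates:
        if cand.length >= 3:
            count = len(cand.respondent_ids)
        else:
            count = cand.fg_count
        out.append(CandidatePhrase(cand.lemmas, count, set(cand.doc_ids),
                                   set(cand.respondent_ids),
                                   list(cand.occurrences)))
    return out


def build_lm(counts, total: int, alpha: float = 0.0,
             vocab_size: int = 0) -> LanguageModel:
    return LanguageModel(counts, total, alpha, vocab_size)


def phraseness(phrase: tuple, ngram_lm: LanguageModel,
               unigram_lm: LanguageModel) -> float:
    """Pointwise KL of the phrase against independence of its words.

    P_fg(phrase) · ln(P_fg(phrase) / ∏ᵢ P_fg(wordᵢ)); exactly 0 for single
    words. Unigram probabilities come from the (unsmoothed) foreground
    model, so a zero unigram probability is a caller error.
    """
    if len(phrase) == 1:
        return 0.0
    p = ngram_lm.prob(phrase)
    if p == 0.0:
        return 0.0
    product = 1.0
    for word in phrase:
        q = unigram_lm.prob((word,))
        if q == 0.0:
            raise ValueError(f"zero foreground unigram probability: {word!r}")
        product *= q
    return p * math.log(p / product)


def informativeness(phrase: tuple, fg_lm: LanguageModel,
                    bg_lm: LanguageModel) -> float:
    """Pointwise KL of foreground vs background probability.

    P_fg(phrase) · ln(P_fg(phrase) / P_bg(phrase)); the background model
    must be smoothed so unseen phrases get a finite floor. Positive for
    phrases over-represented in the foreground, negative for
    under-represented ones.
    """
    p = fg_lm.prob(phrase)
    if p == 0.0:
        return 0.0
    return p * math.log(p / bg_lm.prob(phrase))


def _fg_totals_and_counts(documents: Sequence[Document]):
    """Raw n-gram occurrence totals and unigram counts over the foreground."""
    totals = {n: 0 for n in range(1, MAX_PHRASE_LEN + 1)}
    grams_by_len = {n: set() for n in range(1, MAX_PHRASE_LEN + 1)}
    unigrams = Counter()
    for doc in documents:
        for _, gram in iter_ngrams(doc.tokens):
            totals[len(gram)] += 1
            grams_by_len[len(gram)].add(gram)
            if len(gram) == 1:
                unigrams[gram] += 1
    return totals, grams_by_len, unigrams


def klip_rank(mtg_documents: Sequence[Document],
              background: BackgroundCorpus,
              gamma: float = DEFAULT_GAMMA,
              gamma_weights: str = "informativeness") -> list[PhraseScore]:
    """Rank one group's candidate phrases by the KLIP score.

    klip = γ·informativeness + (1−γ)·phraseness (default orientation;
    ``gamma_weights="phraseness"`` swaps the roles). Candidates are
    extracted, de-duplicated per respondent, and any falling below the
    minimum count afterwards are dropped. Ties are broken by foreground
    count (descending) then lexicographically. An empty candidate set
    yields an empty ranking.
    """
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must be in [0, 1]")
    if gamma_weights not in ("informativeness", "phraseness"):
        raise ValueError(f"unknown gamma_weights: {gamma_weights!r}")
    candidates = dedup_per_respondent(extract_candidates(mtg_documents))
    candidates = [c for c in candidates if c.fg_count >= MIN_FG_COUNT]
    if not candidates:
        return []

    totals, grams_by_len, unigrams = _fg_totals_and_counts(mtg_documents)
    fg_counts = {c.lemmas: c.fg_count for c in candidates}
    unigram_lm = build_lm(unigrams, totals[1])

    scores = []
    for cand in candidates:
        n = cand.length
        fg_lm = build_lm(fg_counts, totals[n])
        union_vocab = grams_by_len[n] | set(background.counts[n])
        bg_lm = build_lm(background.counts[n], background.totals[n],
                         alpha=1.0, vocab_size=len(union_vocab))
        p_score = phraseness(cand.lemmas, fg_lm, unigram_lm)
        i_score = informativeness(cand.lemmas, fg_lm, bg_lm)
        if gamma_weights == "informativeness":
            klip = gamma * i_score + (1.0 - gamma) * p_score
        else:
            klip = gamma * p_score + (1.0 - gamma) * i_score
        scores.append(PhraseScore(cand.lemmas, cand.fg_count, p_score,
                                  i_score, klip, gamma))
    scores.sort(key=lambda s: (-s.klip, -s.fg_count, s.phrase))
    return scores


def rank_by_group(document_set, background: BackgroundCorpus,
                  gamma: float = DEFAULT_GAMMA,
                  gamma_weights: str = "informativeness"
                  ) -> dict[str, list[PhraseScore]]:
    """KLIP ranking per MTG over a prepared document set."""
    return {
        mtg: klip_rank(docs, background, gamma, gamma_weights)
        for mtg, docs in sorted(document_set.by_mtg().items())
    }
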