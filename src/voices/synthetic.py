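"""Synthetic survey cohorts and corpora.

The study data this pipeline targets — a pan-European survey of rare
endocrine disease patients — were never deposited, so every downstream stage
is exercised on synthetic cohorts that carry the same statistical structure:

* demographics drawn with the published cohort's category proportions;
* 3-point priority ratings produced by discretising a Gaussian
  (per-topic baseline + per-(group, topic) mean shift) onto {1, 2, 3};
* open-text answers sampled from planted topic-word distributions, with
  group-specific multi-word phrases inserted at a known rate;
* a generic background corpus standing in for a large reference text
  collection.

Each sub-generator (cohort, text, background) draws from its own stream
derived from the master seed, so adding one generator never perturbs the
draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from voices.errors import ConfigurationError

#: The nine prespecified research topics rated on the 3-point scale.
TOPICS = (
    "heritability",
    "fertility",
    "tiredness",
    "sports",
    "work",
    "social_life",
    "medicine_intake",
    "sleep_quality",
    "physical_discomfort",
)

#: The eight main thematic groups (MTGs) used as the grouping variable.
MTGS = (
    "Adrenal",
    "Calcium-phosphate",
    "Glucose-insulin",
    "Tumour syndromes",
    "Growth-obesity",
    "Pituitary",
    "Sex development",
    "Thyroid",
)

AGE_BANDS = ("<10", "10-18", "19-30", "31-40", "41-50", "51-60", "61-70", ">70")

#: One representative country per region for synthetic respondents.
_REGION_COUNTRIES = {
    "Eastern Europe": ("Poland", "Hungary", "Romania"),
    "Northern Europe": ("Sweden", "Denmark", "United Kingdom"),
    "Southern Europe": ("Italy", "Spain", "Greece"),
    "Western Europe": ("Germany", "Netherlands", "France"),
    "Non-Europe": ("United States", "Japan", "Canada"),
}

# Category proportions of the published cohort (n = 1378).
_DEFAULT_GENDER = {"female": 0.787, "male": 0.206, "undisclosed": 0.007}
_DEFAULT_GROUPS = {
    "Adrenal": 0.391, "Calcium-phosphate": 0.033, "Glucose-insulin": 0.016,
    "Tumour syndromes": 0.054, "Growth-obesity": 0.035, "Pituitary": 0.289,
    "Sex development": 0.051, "Thyroid": 0.131,
}
_DEFAULT_REGIONS = {
    "Eastern Europe": 0.019, "Northern Europe": 0.471,
    "Southern Europe": 0.106, "Western Europe": 0.385, "Non-Europe": 0.019,
}
_DEFAULT_AGES = {
    "<10": 0.015, "10-18": 0.016, "19-30": 0.080, "31-40": 0.168,
    "41-50": 0.282, "51-60": 0.251, "61-70": 0.144, ">70": 0.044,
}
# Whole-cohort topic means as published (priority scale: lower = higher priority).
_DEFAULT_BASELINES = {
    "heritability": 1.55, "fertility": 1.73, "tiredness": 1.30,
    "sports": 1.75, "work": 1.27, "social_life": 1.26,
    "medicine_intake": 1.36, "sleep_quality": 1.33,
    "physical_discomfort": 1.27,
}


def _check_probs(name: str, weights: dict) -> None:
    total = float(sum(weights.values()))
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"{name}: probabilities sum to {total!r}, not 1")
    if any(v < 0 for v in weights.values()):
        raise ConfigurationError(f"{name}: negative probability")


@dataclass
class CohortSpec:
    """Parameters of a synthetic respondent cohort."""

    n_respondents: int
    group_weights: dict = field(default_factory=lambda: dict(_DEFAULT_GROUPS))
    gender_weights: dict = field(default_factory=lambda: dict(_DEFAULT_GENDER))
    region_weights: dict = field(default_factory=lambda: dict(_DEFAULT_REGIONS))
    age_weights: dict = field(default_factory=lambda: dict(_DEFAULT_AGES))
    rating_effects: dict = field(default_factory=dict)  # (mtg, topic) -> shift
    baseline_means: dict = field(default_factory=lambda: dict(_DEFAULT_BASELINES))
    rating_noise_sd: float = 0.7
    missing_rate: float = 0.02
    member_prob: float = 0.685
    patient_prob: float = 0.885
    seed: int = 0

    def validate(self) -> None:
        if self.n_respondents < 0:
            raise ConfigurationError("n_respondents must be non-negative")
        for name in ("group_weights", "gender_weights", "region_weights",
                     "age_weights"):
            _check_probs(name, getattr(self, name))
        if self.rating_noise_sd < 0:
            raise ConfigurationError("rating_noise_sd must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        for topic, mean in self.baseline_means.items():
            if not (1.0 <= mean <= 3.0):
                raise ConfigurationError(
                    f"baseline_means[{topic!r}] = {mean} outside [1, 3]")


@dataclass
class TextSpec:
    """Parameters of synthetic open-text answers and the background corpus."""

    k_true: int
    topic_word_dists: list  # one {word: prob} per planted topic
    doc_length_range: tuple = (8, 30)
    topic_mixing: float = 0.3  # per-word prob of drawing from another topic
    planted_phrases: dict = field(default_factory=dict)  # mtg -> [(phrase, p)]
    background_vocab_dist: dict = field(default_factory=dict)
    question_ids: tuple = ("night", "research")
    seed: int = 0

    def validate(self) -> None:
        if self.k_true < 1:
            raise ConfigurationError("k_true must be >= 1")
        if len(self.topic_word_dists) != self.k_true:
            raise ConfigurationError(
                "topic_word_dists length must equal k_true")
        for i, dist in enumerate(self.topic_word_dists):
            if not dist:
                raise ConfigurationError(f"topic_word_dists[{i}] is empty")
            _check_probs(f"topic_word_dists[{i}]", dist)
        if self.background_vocab_dist:
            _check_probs("background_vocab_dist", self.background_vocab_dist)
        lo, hi = self.doc_length_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("doc_length_range must satisfy 1 <= lo <= hi")
        if not (0.0 <= self.topic_mixing < 1.0):
            raise ConfigurationError("topic_mixing must be in [0, 1)")
        for mtg, phrases in self.planted_phrases.items():
            for phrase, prob in phrases:
                n_words = len(phrase.split())
                if not (2 <= n_words <= 4):
                    raise ConfigurationError(
                        f"planted phrase {phrase!r} for {mtg} must have 2-4 words")
                if not (0 <= prob <= 1):
                    raise ConfigurationError(
                        f"insertion probability for {phrase!r} outside [0, 1]")


def _stream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _draw_labels(rng, weights: dict, n: int) -> np.ndarray:
    labels = np.array(list(weights.keys()), dtype=object)
    probs = np.array(list(weights.values()), dtype=float)
    return rng.choice(labels, size=n, p=probs / probs.sum())


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a synthetic respondent table.

    Each rating is a Gaussian draw (topic baseline + (group, topic) effect,
    sd = ``rating_noise_sd``) rounded to the nearest integer and clamped to
    [1, 3]; a ``missing_rate`` fraction of ratings is blanked completely at
    random. Fully reproducible from ``spec.seed``.
    """
    spec.validate()
    n = spec.n_respondents
    cols = ["respondent_id", "gender", "age_band", "country", "mtg",
            "is_member", "role"] + [f"rating_{t}" for t in TOPICS]
    if n == 0:
        return pd.DataFrame(columns=cols)

    rng = _stream(spec.seed, 0)
    mtg = _draw_labels(rng, spec.group_weights, n)
    gender = _draw_labels(rng, spec.gender_weights, n)
    region = _draw_labels(rng, spec.region_weights, n)
    age = _draw_labels(rng, spec.age_weights, n)
    country = np.array([
        _REGION_COUNTRIES[r][rng.integers(len(_REGION_COUNTRIES[r]))]
        for r in region
    ], dtype=object)
    member = rng.random(n) < spec.member_prob
    role = np.where(rng.random(n) < spec.patient_prob, "patient", "caregiver")

    table = pd.DataFrame({
        "respondent_id": [f"R{i:05d}" for i in range(n)],
        "gender": gender, "age_band": age, "country": country, "mtg": mtg,
        "is_member": member, "role": role,
    })
    for topic in TOPICS:
        mean = np.full(n, spec.baseline_means.get(topic, 2.0))
        for (g, t), shift in spec.rating_effects.items():
            if t == topic:
                mean = mean + np.where(mtg == g, shift, 0.0)
        draw = rng.normal(mean, spec.rating_noise_sd)
        rating = np.clip(np.rint(draw), 1, 3)
        missing = rng.random(n) < spec.missing_rate
        table[f"rating_{topic}"] = np.where(missing, np.nan, rating)
    return table


def generate_open_text(spec: TextSpec, cohort: pd.DataFrame):
    """Generate one open-text document per respondent per open question.

    Each respondent is assigned a primary planted topic; each document word
    is drawn from that topic's word distribution, or — with probability
    ``topic_mixing`` — from a uniformly chosen other topic, so answers touch
    side themes the way real free text does. For respondents of an MTG with
    planted phrases, each phrase is spliced in verbatim at a random position
    with its stated probability.
    """
    from voices.corpus import Document, DocumentSet

    spec.validate()
    if len(cohort) == 0:
        raise ConfigurationError("cohort is empty")

    rng = _stream(spec.seed, 1)
    topic_words = [np.array(list(d.keys()), dtype=object)
                   for d in spec.topic_word_dists]
    topic_probs = [np.asarray(list(d.values()), float) for d in spec.topic_word_dists]
    topic_probs = [p / p.sum() for p in topic_probs]
    lo, hi = spec.doc_length_range

    docs = []
    for _, row in cohort.iterrows():
        z = int(rng.integers(spec.k_true))
        for qid in spec.question_ids:
            length = int(rng.integers(lo, hi + 1))
            sources = np.full(length, z)
            if spec.k_true > 1 and spec.topic_mixing > 0:
                mixed = rng.random(length) < spec.topic_mixing
                others = [t for t in range(spec.k_true) if t != z]
                sources[mixed] = rng.choice(others, size=int(mixed.sum()))
            words = [str(rng.choice(topic_words[s], p=topic_probs[s]))
                     for s in sources]
            for phrase, prob in spec.planted_phrases.get(row["mtg"], ()):
                if rng.random() < prob:
                    pos = int(rng.integers(len(words) + 1))
                    words[pos:pos] = phrase.split()
            docs.append(Document(row["respondent_id"], qid, row["mtg"],
                                 " ".join(words)))
    return DocumentSet(docs, provenance="synthetic")


def generate_background_corpus(spec: TextSpec, n_tokens: int):
    """Generate a desk-scale background corpus from the background vocabulary.

    Emits a token stream of (within 1%) ``n_tokens`` tokens chunked into
    ~20-token lines, and returns the n-gram count tables phrase scoring
    consumes.
    """
    from voices.phrases import BackgroundCorpus

    spec.validate()
    if n_tokens < 1000:
        raise ConfigurationError("n_tokens must be >= 1000")
    if not spec.background_vocab_dist:
        raise ConfigurationError("background_vocab_dist is empty")

    rng = _stream(spec.seed, 2)
    words = np.array(list(spec.background_vocab_dist.keys()), dtype=object)
    probs = np.asarray(list(spec.background_vocab_dist.values()), float)
    tokens = rng.choice(words, size=n_tokens, p=probs / probs.sum())
    lines = [" ".join(tokens[i:i + 20]) for i in range(0, n_tokens, 20)]
    return BackgroundCorpus.from_lines(lines)


# ---------------------------------------------------------------------------
# Default text-generation conditions

_TOPIC_VOCABS = (
    # treatment & medication burden
    ["medication", "dose", "treatment", "side", "effect", "tablet",
     "injection", "therapy", "hormone", "replacement", "dosage", "cortisol",
     "pill", "daily", "intake", "long", "term", "drug", "medicine",
     "substitution", "timing", "schedule", "prescription", "pharmacy",
     "steroid", "growth", "adjust", "monitor", "level", "blood", "test",
     "control", "supply", "availability", "interaction", "safety"],
    # fatigue, sleep & daily function
    ["fatigue", "energy", "sleep", "tiredness", "rest", "night", "work",
     "concentration", "weakness", "recovery", "quality", "life", "social",
     "activity", "pain", "muscle", "joint", "exhaustion", "memory", "mood",
     "stress", "weight", "exercise", "sport", "job", "career", "employer",
     "friend", "family", "holiday", "household", "morning", "focus",
     "headache", "stamina", "confidence"],
    # heredity, fertility & family
    ["fertility", "pregnancy", "child", "gene", "heritability", "family",
     "inheritance", "risk", "mutation", "counselling", "future", "cause",
     "genetic", "screening", "diagnosis", "syndrome", "parent", "research",
     "generation", "daughter", "son", "carrier", "testing", "embryo",
     "conception", "adoption", "puberty", "development", "hereditary",
     "prognosis", "onset", "prevention", "cure", "origin", "variant",
     "sibling"],
)

_SHARED_FILLERS = ["the", "and", "of", "my", "i", "is", "for", "more",
                   "about", "disease", "patient", "doctor"]

_BACKGROUND_VOCAB = [
    "history", "city", "century", "world", "population", "music", "school",
    "country", "government", "language", "river", "mountain", "science",
    "book", "film", "university", "state", "national", "team", "game",
    "water", "art", "building", "road", "company", "market", "people",
    "house", "year", "time", "place", "area", "group", "number", "part",
] + _SHARED_FILLERS

DEFAULT_PLANTED_PHRASES = {
    "Adrenal": [("adrenal crisis", 0.35)],
    "Pituitary": [("restless legs", 0.35)],
    "Thyroid": [("slow release thyroxine", 0.35)],
    "Sex development": [("hearing loss", 0.35)],
    "Tumour syndromes": [("mental health", 0.35)],
}


def _zipf_dist(words: Sequence[str]) -> dict:
    ranks = np.arange(1, len(words) + 1, dtype=float)
    weights = 1.0 / ranks
    weights /= weights.sum()
    return dict(zip(words, weights))


def default_text_spec(k_true: int = 3, seed: int = 0,
                      planted_phrases: dict | None = None) -> TextSpec:
    """Well-separated planted topics emulating short survey answers.

    Each topic mixes a Zipf-weighted themed vocabulary (85% of mass) with a
    shared filler vocabulary including English function words (15%), so that
    documents exercise stop-word masking and the topics remain separable.

    The background distribution mixes generic encyclopedic vocabulary (60%)
    with the ordinary themed words (40%): a realistic generic background
    contains everyday health and life vocabulary at moderate rates, whereas
    the planted group-specific phrases are effectively absent from it —
    which is exactly what makes them, and not common survey words, stand
    out under the informativeness score.
    """
    if not (1 <= k_true <= len(_TOPIC_VOCABS)):
        raise ConfigurationError(
            f"k_true must be in [1, {len(_TOPIC_VOCABS)}] for the default spec")
    dists = []
    filler = _zipf_dist(_SHARED_FILLERS)
    for vocab in _TOPIC_VOCABS[:k_true]:
        themed = _zipf_dist(vocab)
        dist = {w: 0.85 * p for w, p in themed.items()}
        for w, p in filler.items():
            dist[w] = dist.get(w, 0.0) + 0.15 * p
        dists.append(dist)
    if planted_phrases is None:
        planted_phrases = {k: list(v) for k, v in DEFAULT_PLANTED_PHRASES.items()}
    background = {w: 0.6 * p for w, p in _zipf_dist(_BACKGROUND_VOCAB).items()}
    themed = [_zipf_dist(v) for v in _TOPIC_VOCABS]
    for dist in themed:
        for w, p in dist.items():
            background[w] = background.get(w, 0.0) + 0.4 * p / len(themed)
    return TextSpec(
        k_true=k_true,
        topic_word_dists=dists,
        planted_phrases=planted_phrases,
        background_vocab_dist=background,
        seed=seed,
    )


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)
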