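"""Free-text preparation: translation hook, tokenisation, lemmatisation.

Open-field survey answers arrive as raw unicode strings (machine-translated
to English upstream, or synthetic English). This module turns them into
normalised token sequences: lowercased, punctuation stripped, lemmatised,
with stop words *marked but never removed* — downstream phrase extraction
needs original token adjacency to enforce its boundary rules, while topic
modelling drops masked tokens from its vocabulary.

The lemmatiser is a deterministic rule-based one (plural stripping, -ing/-ed
reduction, a small irregular-form table) behind a pluggable interface, so
that fixtures and results are reproducible without a heavyweight model.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_VOWELS = set("aeiou")

#: Inflected forms the suffix rules would mangle or miss.
_IRREGULAR = {
    "is": "be", "am": "be", "are": "be", "was": "be", "were": "be",
    "has": "have", "does": "do", "goes": "go", "went": "go", "going": "go",
    "children": "child", "men": "man", "women": "woman", "feet": "foot",
    "teeth": "tooth", "mice": "mouse", "lives": "life", "wives": "wife",
    "knives": "knife", "selves": "self",
}

#: Words that look suffixed but are base forms.
_NO_STRIP = {
    "morning", "evening", "nothing", "something", "anything", "everything",
    "during", "tired", "used", "needed", "news", "less", "stress",
    "diabetes", "series", "species",
}


def _load_stopwords() -> frozenset[str]:
    text = resources.files("voices.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


STOPWORDS: frozenset[str] = _load_stopwords()


def _cvc_restore(stem: str) -> str:
    # consonant-vowel-consonant ending usually lost a silent e (tak -> take)
    if (
        len(stem) >= 3
        and stem[-1] not in _VOWELS and stem[-1] not in "wxy"
        and stem[-2] in _VOWELS
        and stem[-3] not in _VOWELS
    ):
        return stem + "e"
    return stem


def _strip_suffix(stem: str) -> str:
    # doubled final consonant (running -> run) and silent-e loss
    # (taking -> take) are mutually exclusive repairs
    if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in "aeioulsz":
        return stem[:-1]
    return _cvc_restore(stem)


def lemmatize(word: str) -> str:
    """Reduce an inflected lowercase word to its dictionary form.

    Rule-based and deterministic: irregular table first, then plural
    stripping (-ies/-es/-s) and verb-suffix reduction (-ing/-ed) with
    doubled-consonant and silent-e repair. Idempotent on its own output.
    """
    if word in _IRREGULAR:
        return _IRREGULAR[word]
    if word in _NO_STRIP or word in STOPWORDS or len(word) <= 3:
        return word
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("ied") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("ches", "shes", "xes", "zes", "sses")):
        return word[:-2]
    if word.endswith("s") and not word.endswith(("ss", "us", "is")):
        return word[:-1]
    if word.endswith("ing") and len(word) >= 6:
        stem = word[:-3]
        return _strip_suffix(stem)
    if word.endswith("ed") and len(word) >= 5:
        stem = word[:-2]
        return _strip_suffix(stem)
    return word


def tokenize_lemmatize(
    text: str, lemmatizer: Callable[[str], str] = lemmatize
) -> tuple[list[str], list[bool]]:
    """Tokenise and lemmatise a text; mark (never remove) stop words.

    Returns ``(tokens, stopword_mask)`` of equal length. Tokens are
    lowercased, punctuation-free lemmas; numerals are retained. A token is
    masked as a stop word if either its surface form or its lemma is on the
    shipped stop list.
    """
    raw = _TOKEN_RE.findall(text.lower().replace("'", ""))
    tokens: list[str] = []
    mask: list[bool] = []
    for surface in raw:
        lemma = lemmatizer(surface)
        tokens.append(lemma)
        mask.append(surface in STOPWORDS or lemma in STOPWORDS)
    return tokens, mask


@dataclass
class Document:
    """One open-field answer by one respondent.

    ``tokens`` and ``stopword_mask`` are filled by :func:`prepare`; raw
    documents carry only ``raw_text``.
    """

    respondent_id: str
    question_id: str
    mtg: str
    raw_text: str
    tokens: list[str] = field(default_factory=list)
    stopword_mask: list[bool] = field(default_factory=list)

    def content_tokens(self) -> list[str]:
        """Tokens with stop words dropped (topic-modelling view)."""
        return [t for t, s in zip(self.tokens, self.stopword_mask) if not s]


@dataclass
class DocumentSet:
    """A collection of documents with group indices and provenance."""

    documents: list[Document]
    provenance: str = "identity"

    def by_mtg(self) -> dict[str, list[Document]]:
        groups: dict[str, list[Document]] = {}
        for doc in self.documents:
            groups.setdefault(doc.mtg, []).append(doc)
        return groups

    def by_question(self) -> dict[str, list[Document]]:
        groups: dict[str, list[Document]] = {}
        for doc in self.documents:
            groups.setdefault(doc.question_id, []).append(doc)
        return groups

    def __len__(self) -> int:
        return len(self.documents)


def identity_translator(text: str) -> str:
    return text


def translate(
    document_set: DocumentSet,
    translator: Callable[[str], str] = identity_translator,
    name: str | None = None,
) -> tuple[DocumentSet, list[str]]:
    """Apply a pluggable translator to every document's raw text.

    The default identity translator is a bit-exact pass-through. A document
    on which the translator raises is retained untranslated and its
    respondent/question ids are returned in the failure log — documents are
    never silently dropped.
    """
    out: list[Document] = []
    failures: list[str] = []
    for doc in document_set.documents:
        try:
            text = translator(doc.raw_text)
        except Exception:
            failures.append(f"{doc.respondent_id}/{doc.question_id}")
            text = doc.raw_text
        out.append(Document(doc.respondent_id, doc.question_id, doc.mtg, text,
                            list(doc.tokens), list(doc.stopword_mask)))
    label = name or getattr(translator, "__name__", "translator")
    return DocumentSet(out, provenance=label), failures


def prepare(
    document_set: DocumentSet,
    lemmatizer: Callable[[str], str] = lemmatize,
) -> DocumentSet:
    """Tokenise and lemmatise every document; fills tokens + stop-word mask."""
    out = []
    for doc in document_set.documents:
        tokens, mask = tokenize_lemmatize(doc.raw_text, lemmatizer)
        out.append(Document(doc.respondent_id, doc.question_id, doc.mtg,
                            doc.raw_text, tokens, mask))
    return DocumentSet(out, provenance=document_set.provenance)


def combine_questions(
    document_set: DocumentSet, question_ids: Sequence[str]
) -> DocumentSet:
    """Pool the documents of the named questions into one analysis set.

    Each answer stays a distinct document (answers are weighted equally) and
    keeps its respondent attribution, which per-respondent de-duplication in
    phrase extraction relies on.
    """
    ids = set(question_ids)
    present = {d.question_id for d in document_set.documents}
    missing = ids - present
    if missing:
        raise KeyError(f"question ids not in document set: {sorted(missing)}")
    docs = [d for d in document_set.documents if d.question_id in ids]
    return DocumentSet(docs, provenance=document_set.provenance)


def write_jsonl(document_set: DocumentSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in document_set.documents:
            rec = {
                "respondent_id": doc.respondent_id,
                "question_id": doc.question_id,
                "mtg": doc.mtg,
                "text": doc.raw_text,
            }
            if doc.tokens:
                rec["tokens"] = doc.tokens
                rec["stopword_mask"] = doc.stopword_mask
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_jsonl(path) -> DocumentSet:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            docs.append(Document(
                rec["respondent_id"], rec["question_id"], rec["mtg"],
                rec["text"], rec.get("tokens", []),
                rec.get("stopword_mask", []),
            ))
    return DocumentSet(docs)
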