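"""Corpus pre-processing: sentence segmentation, tokenisation, phrase induction.

The vocabulary a clinical corpus yields is deliberately raw: terms are
lowercased surface forms, with no stemming, lemmatisation or spell
correction, so that the downstream embedding sees clinician language
exactly as written.  Frequent adjacent token pairs are joined into
underscore-delimited n-gram tokens (two passes: bigrams, then trigrams)
so that fixed collocations such as ``eye_contact`` become single
vocabulary entries.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Protocol

__all__ = [
    "Document",
    "Corpus",
    "SentenceSegmenter",
    "RegexSentenceSegmenter",
    "segment_and_tokenize",
    "PhraseModel",
    "learn_phrases",
    "apply_phrases",
    "phrase_corpus",
    "Vocabulary",
    "VocabularySummary",
    "build_vocabulary",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
]


# --------------------------------------------------------------------------
# Corpus container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Document:
    """One free-text record attributed to a patient."""

    patient_id: str
    doc_id: str
    text: str


@dataclass
class Corpus:
    """Patient-attributed free-text documents with unique document ids."""

    documents: list[Document]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise ValueError(f"duplicate doc_id: {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)


def write_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            rec = {"patient_id": doc.patient_id, "doc_id": doc.doc_id, "text": doc.text}
            fh.write(json.dumps(rec) + "\n")


def read_corpus_jsonl(path: str | Path) -> Corpus:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            docs.append(Document(rec["patient_id"], rec["doc_id"], rec["text"]))
    return Corpus(docs)


# --------------------------------------------------------------------------
# Sentence segmentation and tokenisation
# --------------------------------------------------------------------------

class SentenceSegmenter(Protocol):
    """Interface for sentence boundary detection.

    Kept behind a protocol so an unsupervised boundary model can be
    swapped in where one is available; the default is a rule-based
    segmenter splitting on terminal punctuation.
    """

    def segment(self, text: str) -> list[str]: ...


_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+")
# word runs (letters/digits/apostrophes) or any single non-space symbol
_TOKEN = re.compile(r"[a-z0-9']+|[^\sa-z0-9']")


class RegexSentenceSegmenter:
    """Rule-based segmenter: sentence boundaries after ``.``, ``!`` or ``?``."""

    def segment(self, text: str) -> list[str]:
        parts = _SENT_BOUNDARY.split(text.strip())
        return [p for p in (s.strip() for s in parts) if p]


_DEFAULT_SEGMENTER = RegexSentenceSegmenter()


def segment_and_tokenize(
    text: str, segmenter: SentenceSegmenter | None = None
) -> list[list[str]]:
    """Split free text into sentences of lowercase tokens.

    Degenerate inputs (empty or whitespace-only text) yield an empty
    list rather than an error.
    """
    if segmenter is None:
        segmenter = _DEFAULT_SEGMENTER
    sentences = []
    for sent in segmenter.segment(text):
        tokens = _TOKEN.findall(sent.lower())
        if tokens:
            sentences.append(tokens)
    return sentences


def tokenize_corpus(
    corpus: Corpus, segmenter: SentenceSegmenter | None = None
) -> list[list[list[str]]]:
    """Tokenise every document; returns per-document sentence lists."""
    return [segment_and_tokenize(doc.text, segmenter) for doc in corpus]


# --------------------------------------------------------------------------
# Phrase induction
# --------------------------------------------------------------------------

def _is_wordlike(token: str) -> bool:
    return any(c.isalpha() for c in token)


def _order(token: str) -> int:
    return token.count("_") + 1


@dataclass
class PhraseModel:
    """Learnt collocations, one ``(left, right) -> score`` map per pass."""

    passes: list[dict[tuple[str, str], float]] = field(default_factory=list)
    min_count: int = 10
    threshold: float = 10.0

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("pass\tleft\tright\tscore\n")
            for p, table in enumerate(self.passes):
                for (a, b), score in sorted(table.items()):
                    fh.write(f"{p}\t{a}\t{b}\t{score:.6g}\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "PhraseModel":
        passes: list[dict[tuple[str, str], float]] = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if header.strip() != "pass\tleft\tright\tscore":
                raise ValueError("malformed phrase model file")
            for line in fh:
                p_s, a, b, score = line.rstrip("\n").split("\t")
                p = int(p_s)
                while len(passes) <= p:
                    passes.append({})
                passes[p][(a, b)] = float(score)
        return cls(passes=passes)


def _learn_single_pass(
    sentences: Iterable[list[str]],
    min_count: int,
    threshold: float,
    max_order: int,
) -> dict[tuple[str, str], float]:
    unigram: Counter[str] = Counter()
    bigram: Counter[tuple[str, str]] = Counter()
    n_tokens = 0
    for sent in sentences:
        n_tokens += len(sent)
        unigram.update(sent)
        for a, b in zip(sent, sent[1:]):
            if not (_is_wordlike(a) and _is_wordlike(b)):
                continue
            if _order(a) + _order(b) > max_order:
                continue
            bigram[(a, b)] += 1
    table: dict[tuple[str, str], float] = {}
    for (a, b), c_ab in bigram.items():
        if c_ab < min_count:
            continue
        # discounted pointwise score; the min_count doubles as the discount
        score = (c_ab - min_count) * n_tokens / (unigram[a] * unigram[b])
        if score >= threshold:
            table[(a, b)] = score
    return table


def _apply_single_pass(
    sentence: list[str], table: dict[tuple[str, str], float]
) -> list[str]:
    out: list[str] = []
    i = 0
    while i < len(sentence):
        if i + 1 < len(sentence) and (sentence[i], sentence[i + 1]) in table:
            out.append(sentence[i] + "_" + sentence[i + 1])
            i += 2
        else:
            out.append(sentence[i])
            i += 1
    return out


def learn_phrases(
    sentences: list[list[str]],
    min_count: int = 10,
    threshold: float = 10.0,
    passes: int = 2,
) -> PhraseModel:
    """Learn underscore-joined collocations over a flat sentence list.

    A pair ``(a, b)`` is joined iff ``count(ab) >= min_count`` and
    ``(count(ab) - min_count) * N / (count(a) * count(b)) >= threshold``
    with ``N`` the corpus token count.  Pass 1 induces bigrams; pass 2
    runs over the bigram-joined text so trigrams emerge as
    bigram + unigram joins.  Joined tokens never exceed trigram order.
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    if not sentences:
        raise ValueError("phrase learning requires a non-empty corpus")
    model = PhraseModel(passes=[], min_count=min_count, threshold=threshold)
    current = sentences
    for _ in range(passes):
        table = _learn_single_pass(current, min_count, threshold, max_order=3)
        model.passes.append(table)
        current = [_apply_single_pass(s, table) for s in current]
    return model


def apply_phrases(sentence: list[str], model: PhraseModel) -> list[str]:
    """Greedy left-to-right phrase joining; idempotent on joined text."""
    out = sentence
    for table in model.passes:
        out = _apply_single_pass(out, table)
    return out


def phrase_corpus(
    docs: list[list[list[str]]], model: PhraseModel
) -> list[list[list[str]]]:
    """Apply the phrase model to every sentence of every document."""
    return [[apply_phrases(s, model) for s in doc] for doc in docs]


# --------------------------------------------------------------------------
# Vocabulary
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VocabularySummary:
    """Per-class vocabulary subtotals; word n-grams and non-words partition
    the vocabulary, so the total is their sum."""

    unigrams: int
    bigrams: int
    trigrams: int
    non_word: int

    @property
    def total(self) -> int:
        return self.unigrams + self.bigrams + self.trigrams + self.non_word


@dataclass(frozen=True)
class VocabEntry:
    count: int
    order: int
    is_word: bool


class Vocabulary:
    """Term -> (count, n-gram order, word flag) with exact corpus counts."""

    def __init__(self, entries: dict[str, VocabEntry]):
        self._entries = entries

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, term: str) -> bool:
        return term in self._entries

    def __getitem__(self, term: str) -> VocabEntry:
        return self._entries[term]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def items(self):
        return self._entries.items()

    def count(self, term: str) -> int:
        return self._entries[term].count

    def summary(self) -> VocabularySummary:
        uni = bi = tri = nonword = 0
        for entry in self._entries.values():
            if not entry.is_word:
                nonword += 1
            elif entry.order == 1:
                uni += 1
            elif entry.order == 2:
                bi += 1
            else:
                tri += 1
        return VocabularySummary(uni, bi, tri, nonword)

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("term\tcount\torder\tis_word\n")
            for term, e in sorted(self._entries.items()):
                fh.write(f"{term}\t{e.count}\t{e.order}\t{int(e.is_word)}\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "Vocabulary":
        entries: dict[str, VocabEntry] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if header.strip() != "term\tcount\torder\tis_word":
                raise ValueError("malformed vocabulary file")
            for line in fh:
                term, count, order, is_word = line.rstrip("\n").split("\t")
                entries[term] = VocabEntry(int(count), int(order), bool(int(is_word)))
        return cls(entries)


def build_vocabulary(docs: list[list[list[str]]]) -> Vocabulary:
    """Count every term of a phrased corpus.

    Order is the underscore-implied n-gram size (capped at 3); a term is
    a word entity iff it contains at least one alphabetic character.
    """
    counts: Counter[str] = Counter()
    for doc in docs:
        for sent in doc:
            counts.update(sent)
    entries = {
        term: VocabEntry(count=c, order=min(_order(term), 3), is_word=_is_wordlike(term))
        for term, c in counts.items()
    }
    return Vocabulary(entries)
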