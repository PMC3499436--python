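"""Keyword scoring of a query text by sentence co-occurrence.

Each content word receives a graded (fuzzy) pairwise relation to every other
word based on how often they appear in the same sentence: with ``s(i)`` the
number of sentences containing term *i* and ``s(i, j)`` the number
containing both *i* and *j*,

    mu(i, j) = s(i, j)^2 / (s(i) * s(j))        in [0, 1].

A word's raw keyword score is the sum of its relations; final scores are
normalized by the maximum, so the best-connected word scores 1. Frequent
words with many strong relations therefore rank highest. A query profile
keeps at most ``max_terms`` terms with score strictly above ``min_score``.

Tokens are lower-cased, stop words removed, and — when a part-of-speech
tagger is plugged in — restricted to nouns, adjectives and verbs. The
default build uses the null tagger (stop-word filtering only) plus the
shipped English stop-word list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Protocol, Sequence

__all__ = [
    "Tagger",
    "SentenceSet",
    "KeywordProfile",
    "default_stopwords",
    "load_stopwords",
    "split_sentences",
    "split_and_filter",
    "relation_strength",
    "keyword_scores",
    "extract_keywords",
]

CONTENT_POS = frozenset({"NOUN", "ADJ", "VERB"})


class Tagger(Protocol):
    """Pluggable part-of-speech tagger.

    ``tag`` receives the tokens of one sentence and returns one coarse tag
    per token; tags in ``{"NOUN", "ADJ", "VERB"}`` mark content words.
    """

    def tag(self, tokens: Sequence[str]) -> Sequence[str]: ...


@dataclass(frozen=True)
class SentenceSet:
    """Sentences of a text as lists of filtered, lower-cased content words."""

    sentences: tuple[tuple[str, ...], ...]

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    @property
    def vocabulary(self) -> set[str]:
        return {t for sent in self.sentences for t in sent}


@dataclass(frozen=True)
class KeywordProfile:
    """Bounded, thresholded list of (term, score), best first.

    Scores lie in (min_score, 1]; ties order lexicographically by term.
    """

    entries: tuple[tuple[str, float], ...]
    max_terms: int = 50
    min_score: float = 0.05

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.entries)

    def as_dict(self) -> dict[str, float]:
        return dict(self.entries)


def load_stopwords(path) -> frozenset[str]:
    """Load a stop-word list: one token per line, UTF-8, '#' comments."""
    with open(path, encoding="utf-8") as fh:
        return frozenset(
            w for w in (line.strip().lower() for line in fh)
            if w and not w.startswith("#")
        )


def default_stopwords() -> frozenset[str]:
    text = resources.files("peerfind").joinpath("data/stopwords.txt").read_text("utf-8")
    return frozenset(
        w for w in (line.strip().lower() for line in text.splitlines())
        if w and not w.startswith("#")
    )


_DEFAULT_ABBREVIATIONS = frozenset({
    "e.g.", "i.e.", "et al.", "cf.", "vs.", "fig.", "figs.", "dr.", "prof.",
    "approx.", "ca.", "resp.", "no.", "spp.", "sp.",
})

_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+")
_TOKEN = re.compile(r"[^\W\d_][\w'-]*", re.UNICODE)


def split_sentences(text: str, abbreviations: frozenset[str] = _DEFAULT_ABBREVIATIONS) -> list[str]:
    """Split on terminal punctuation followed by whitespace.

    A candidate boundary is rejected when the text before it ends in a known
    abbreviation, or when the next character is not an upper-case letter,
    digit or opening quote/bracket (simple boundary heuristic). Text without
    terminal punctuation is one sentence.
    """
    pieces: list[str] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        left = text[start:m.start() + 1]
        nxt = text[m.end():m.end() + 1]
        strip_open = "([{\"'"
        words = [w.lstrip(strip_open) for w in left.rstrip().lower().split()]
        last_word = words[-1] if words else ""
        two_words = " ".join(words[-2:])
        if last_word in abbreviations or two_words in abbreviations:
            continue
        if nxt and not (nxt.isupper() or nxt.isdigit() or nxt in "\"'([{"):
            continue
        pieces.append(left)
        start = m.end()
    tail = text[start:]
    if tail.strip():
        pieces.append(tail)
    return [p.strip() for p in pieces if p.strip()]


def split_and_filter(
    text: str,
    stopwords: Iterable[str] | None = None,
    tagger: Tagger | None = None,
    keep_pos: frozenset[str] = CONTENT_POS,
) -> SentenceSet:
    """Tokenize ``text`` into a :class:`SentenceSet` of content words.

    Tokens are lower-cased; stop words removed; with a tagger, only tokens
    tagged in ``keep_pos`` survive (the null tagger ``None`` applies
    stop-word filtering alone). Empty text yields an empty set.
    """
    stop = frozenset(stopwords) if stopwords is not None else default_stopwords()
    out: list[tuple[str, ...]] = []
    for sentence in split_sentences(text):
        tokens = [t.lower() for t in _TOKEN.findall(sentence)]
        if tagger is not None and tokens:
            tags = tagger.tag(tokens)
            tokens = [t for t, tag in zip(tokens, tags) if tag in keep_pos]
        tokens = [t for t in tokens if t not in stop]
        if tokens:
            out.append(tuple(tokens))
    return SentenceSet(sentences=tuple(out))


def _sentence_counts(sentence_set: SentenceSet) -> tuple[dict[str, int], dict[tuple[str, str], int]]:
    """s(i) and s(i,j) over unordered term pairs (presence per sentence)."""
    single: dict[str, int] = {}
    pair: dict[tuple[str, str], int] = {}
    for sent in sentence_set:
        terms = sorted(set(sent))
        for t in terms:
            single[t] = single.get(t, 0) + 1
        for a_i, a in enumerate(terms):
            for b in terms[a_i + 1:]:
                pair[(a, b)] = pair.get((a, b), 0) + 1
    return single, pair


def relation_strength(sentence_set: SentenceSet) -> dict[tuple[str, str], float]:
    """Fuzzy relation mu(i,j) = s(i,j)^2 / (s(i)*s(j)) for co-occurring pairs.

    Returned symmetric: both (i, j) and (j, i) are present. Pairs that never
    co-occur are absent (mu = 0).
    """
    single, pair = _sentence_counts(sentence_set)
    mu: dict[tuple[str, str], float] = {}
    for (a, b), sij in pair.items():
        value = sij * sij / (single[a] * single[b])
        mu[(a, b)] = value
        mu[(b, a)] = value
    return mu


def keyword_scores(sentence_set: SentenceSet) -> dict[str, float]:
    """Normalized keyword score per term.

    Raw score r(i) = sum over j of mu(i,j); final k(i) = r(i) / max r. When
    no pair ever co-occurs all scores are zero.
    """
    mu = relation_strength(sentence_set)
    raw: dict[str, float] = {t: 0.0 for t in sentence_set.vocabulary}
    for (a, _b), value in mu.items():
        raw[a] += value
    top = max(raw.values(), default=0.0)
    if top == 0.0:
        return raw
    return {t: r / top for t, r in raw.items()}


def extract_keywords(
    text: str,
    max_terms: int = 50,
    min_score: float = 0.05,
    stopwords: Iterable[str] | None = None,
    tagger: Tagger | None = None,
) -> KeywordProfile:
    """Build the bounded, thresholded keyword profile of ``text``.

    Keeps the top ``max_terms`` terms with score strictly greater than
    ``min_score``, sorted by descending score then term. Too-short text
    yields an empty profile; the caller decides how to report that.
    """
    sentence_set = split_and_filter(text, stopwords=stopwords, tagger=tagger)
    scores = keyword_scores(sentence_set)
    kept = sorted(
        ((t, s) for t, s in scores.items() if s > min_score),
        key=lambda ts: (-ts[1], ts[0]),
    )[:max_terms]
    return KeywordProfile(entries=tuple(kept), max_terms=max_terms, min_score=min_score)
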