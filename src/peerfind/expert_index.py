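"""Term-based retrieval over expert profiles.

Profiles are indexed in an inverted index and ranked against a query
keyword profile with a classic practical TF-IDF similarity: for a query q
and profile d,

    score(q, d) = coord(q, d) * sum over overlapping terms t of
                  w_q(t) * idf(t)^2 * sqrt(tf(t, d)) / sqrt(|d|)

where w_q(t) is the query keyword score, idf(t) = 1 + ln(N / (df(t) + 1))
floored at a small positive value, |d| the profile's total token count, and
coord the fraction of query terms matched. Candidates can be pre-filtered
to authors who published in journals mapped to chosen broad subjects; the
filter never changes a surviving author's score (idf stays computed over
the full index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

from .keyword_extraction import KeywordProfile
from .profiles import ExpertProfile

__all__ = [
    "InvertedIndex",
    "RankedExpert",
    "NoKeywordsError",
    "EmptyStoreError",
    "build_index",
    "idf",
    "score_expert",
    "search",
    "journal_table",
    "read_subject_map",
    "write_results_tsv",
]

IDF_FLOOR = 1e-6
N_DISPLAY_KEYWORDS = 10


class NoKeywordsError(ValueError):
    """The query profile has no keywords (e.g. a too-short abstract)."""


class EmptyStoreError(ValueError):
    """An index cannot be built from an empty profile store."""


@dataclass
class InvertedIndex:
    """Postings, document frequencies and length norms over profiles."""

    postings: dict[str, list[tuple[str, int]]]
    doc_freq: dict[str, int]
    n_docs: int
    doc_len: dict[str, int]
    _tf: dict[str, dict[str, int]] = field(default_factory=dict, repr=False)

    def tf(self, term: str, author_id: str) -> int:
        return self._tf.get(term, {}).get(author_id, 0)


@dataclass(frozen=True)
class RankedExpert:
    """One search hit, with display keywords from the expert's profile."""

    author_id: str
    score: float
    display_keywords: tuple[str, ...]
    anchor_coauthor: str | None
    n_refs: int


def build_index(profile_store: Iterable[ExpertProfile]) -> InvertedIndex:
    """Build the inverted index over indexable profiles.

    Deterministic regardless of store order: postings are sorted by
    author_id. Duplicate author ids or an effectively empty store raise.
    """
    tf: dict[str, dict[str, int]] = {}
    doc_len: dict[str, int] = {}
    for profile in profile_store:
        if profile.author_id in doc_len:
            raise ValueError(f"duplicate author_id {profile.author_id!r}")
        if not profile.indexable:
            continue
        doc_len[profile.author_id] = profile.total_tokens
        for term, count in profile.term_counts.items():
            tf.setdefault(term, {})[profile.author_id] = count
    if not doc_len:
        raise EmptyStoreError("no indexable profiles")
    postings = {
        term: sorted(by_doc.items()) for term, by_doc in sorted(tf.items())
    }
    doc_freq = {term: len(by_doc) for term, by_doc in postings.items()}
    return InvertedIndex(
        postings=postings, doc_freq=doc_freq, n_docs=len(doc_len),
        doc_len=doc_len, _tf=tf,
    )


def idf(term: str, index: InvertedIndex) -> float:
    """1 + ln(N/(df+1)), floored at a small positive value.

    The floor avoids negative contributions for terms present in most
    profiles of tiny corpora.
    """
    df = index.doc_freq.get(term, 0)
    return max(1.0 + math.log(index.n_docs / (df + 1)), IDF_FLOOR)


def score_expert(query: KeywordProfile, author_id: str, index: InvertedIndex) -> float:
    """TF-IDF similarity between the query profile and one expert."""
    if author_id not in index.doc_len:
        raise KeyError(f"author {author_id!r} not indexed")
    if len(query) == 0:
        return 0.0
    norm = 1.0 / math.sqrt(index.doc_len[author_id])
    overlap = 0
    acc = 0.0
    for term, weight in query:
        tf = index.tf(term, author_id)
        if tf == 0:
            continue
        overlap += 1
        term_idf = idf(term, index)
        acc += weight * term_idf * term_idf * math.sqrt(tf) * norm
    if overlap == 0:
        return 0.0
    coord = overlap / len(query)
    return coord * acc


def _display_keywords(profile: ExpertProfile, index: InvertedIndex,
                      n: int = N_DISPLAY_KEYWORDS) -> tuple[str, ...]:
    """Top profile terms by tf*idf — the expert's most distinctive words."""
    ranked = sorted(
        profile.term_counts,
        key=lambda t: (-profile.term_counts[t] * idf(t, index), t),
    )
    return tuple(ranked[:n])


def search(
    query: KeywordProfile,
    index: InvertedIndex,
    profile_store: Mapping[str, ExpertProfile],
    top_k: int = 20,
    subjects: Sequence[str] | None = None,
    subject_map: Mapping[str, set[str]] | None = None,
) -> list[RankedExpert]:
    """Rank candidate reviewers for a query keyword profile.

    With ``subjects``, candidates restrict to authors having at least one
    citation in a journal mapped to any selected subject; idf stays
    computed over the full index, so a surviving author's score is
    unchanged by the filter. Results sort by descending score, ties by
    author_id.
    """
    if len(query) == 0:
        raise NoKeywordsError(
            "query text produced no keywords; supply a longer abstract"
        )
    if subjects is not None and subject_map is None:
        raise ValueError("subject filtering requires a subject_map")

    candidates = sorted(index.doc_len)
    if subjects:
        wanted = set(subjects)
        candidates = [
            aid for aid in candidates
            if any(
                wanted & subject_map.get(journal, set())
                for journal in profile_store[aid].journals
            )
        ]
    scored = [(score_expert(query, aid, index), aid) for aid in candidates]
    scored.sort(key=lambda sa: (-sa[0], sa[1]))
    results = []
    for score, aid in scored[:top_k]:
        profile = profile_store[aid]
        results.append(
            RankedExpert(
                author_id=aid,
                score=score,
                display_keywords=_display_keywords(profile, index),
                anchor_coauthor=profile.anchor_coauthor,
                n_refs=profile.n_refs,
            )
        )
    return results


def journal_table(
    results: Sequence[RankedExpert], profile_store: Mapping[str, ExpertProfile]
) -> list[tuple[str, int]]:
    """Journals where the returned experts have published, with the count of
    distinct experts per journal, most shared first."""
    counts: dict[str, int] = {}
    for hit in results:
        for journal in profile_store[hit.author_id].journals:
            counts[journal] = counts.get(journal, 0) + 1
    return sorted(counts.items(), key=lambda jc: (-jc[1], jc[0]))


def read_subject_map(stream: IO[str]) -> dict[str, set[str]]:
    """TSV of (journal_id, subject), one pair per line."""
    mapping: dict[str, set[str]] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        journal, subject = line.split("\t")
        mapping.setdefault(journal, set()).add(subject)
    return mapping


def write_results_tsv(results: Sequence[RankedExpert], stream: IO[str]) -> None:
    stream.write("rank\tauthor_id\tscore\tanchor_coauthor\tn_refs\tkeywords\n")
    for rank, hit in enumerate(results, start=1):
        stream.write(
            "\t".join(
                [
                    str(rank),
                    hit.author_id,
                    f"{hit.score:.6g}",
                    hit.anchor_coauthor or "-",
                    str(hit.n_refs),
                    ";".join(hit.display_keywords),
                ]
            )
            + "\n"
        )
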