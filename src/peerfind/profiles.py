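"""Expertise profiles for disambiguated authors.

An author's expertise is represented as the term-frequency vector over the
abstracts of all references attributed to their disambiguated identity,
using the same tokenization contract as the query side (with a tagger,
profile terms restrict to nouns; with the null tagger, stop-word filtering
alone) so that query and profile vocabularies stay symmetric.

Only authors with at least one attributed citation as first or last author
within the configured year window (default 2000-2010) and journal list are
indexed — the pool of plausibly active, senior-enough reviewers.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

from .disambiguation import DisambiguatedAuthor
from .keyword_extraction import Tagger, split_and_filter
from .records_io import CitationCorpus

__all__ = [
    "ExpertProfile",
    "is_eligible",
    "build_expert_profile",
    "write_profile_store",
    "read_profile_store",
]


@dataclass(frozen=True)
class ExpertProfile:
    """Term-frequency expertise vector for one disambiguated author."""

    author_id: str
    term_counts: dict[str, int]
    n_abstracts: int
    journals: frozenset[str]
    years: frozenset[int]
    anchor_coauthor: str | None
    n_refs: int

    @property
    def indexable(self) -> bool:
        """False when every attributed abstract was empty."""
        return bool(self.term_counts)

    @property
    def total_tokens(self) -> int:
        return sum(self.term_counts.values())


def is_eligible(
    author: DisambiguatedAuthor,
    corpus: CitationCorpus,
    journal_set: frozenset[str] | set[str] = frozenset(),
    year_min: int = 2000,
    year_max: int = 2010,
) -> bool:
    """True iff some attributed citation has the author first or last,
    within [year_min, year_max] (inclusive), in a listed journal.

    An empty ``journal_set`` means no journal restriction. A single-author
    paper counts as both first and last.
    """
    for pmid in author.pmids:
        cit = corpus.get(pmid)
        keys = cit.author_keys
        if author.name_key not in (keys[0], keys[-1]):
            continue
        if not (year_min <= cit.year <= year_max):
            continue
        if journal_set and cit.journal_id not in journal_set:
            continue
        return True
    return False


def build_expert_profile(
    author: DisambiguatedAuthor,
    corpus: CitationCorpus,
    stopwords: Iterable[str] | None = None,
    tagger: Tagger | None = None,
) -> ExpertProfile:
    """Build the term-frequency profile over the author's abstracts.

    With a tagger the vocabulary restricts to nouns; the null tagger falls
    back to stop-word filtering, matching the query-side contract.
    Citations without an abstract contribute nothing to the counts but still
    count toward journals and years.
    """
    counts: Counter[str] = Counter()
    journals: set[str] = set()
    years: set[int] = set()
    n_abstracts = 0
    stop = frozenset(stopwords) if stopwords is not None else None
    for pmid in sorted(author.pmids):
        cit = corpus.get(pmid)
        journals.add(cit.journal_id)
        years.add(cit.year)
        if not cit.abstract.strip():
            continue
        n_abstracts += 1
        sentence_set = split_and_filter(
            cit.abstract, stopwords=stop, tagger=tagger,
            keep_pos=frozenset({"NOUN"}),
        )
        for sent in sentence_set:
            counts.update(sent)
    return ExpertProfile(
        author_id=author.author_id,
        term_counts=dict(counts),
        n_abstracts=n_abstracts,
        journals=frozenset(journals),
        years=frozenset(years),
        anchor_coauthor=author.anchor_coauthor,
        n_refs=author.n_refs,
    )


def write_profile_store(profiles: Iterable[ExpertProfile], stream: IO[str]) -> None:
    """One JSON object per line, deterministic key order."""
    for p in profiles:
        obj = {
            "author_id": p.author_id,
            "anchor": p.anchor_coauthor,
            "n_abstracts": p.n_abstracts,
            "n_refs": p.n_refs,
            "journals": sorted(p.journals),
            "years": sorted(p.years),
            "term_counts": {t: p.term_counts[t] for t in sorted(p.term_counts)},
        }
        stream.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_profile_store(stream: IO[str]) -> Iterator[ExpertProfile]:
    for line in stream:
        if not line.strip():
            continue
        obj = json.loads(line)
        yield ExpertProfile(
            author_id=obj["author_id"],
            term_counts=dict(obj["term_counts"]),
            n_abstracts=int(obj["n_abstracts"]),
            journals=frozenset(obj["journals"]),
            years=frozenset(int(y) for y in obj["years"]),
            anchor_coauthor=obj.get("anchor"),
            n_refs=int(obj.get("n_refs", 0)),
        )
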