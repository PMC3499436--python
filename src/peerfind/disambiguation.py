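"""Coauthor-based author-name disambiguation.

Many distinct scientists share one ``lastname_initials`` key. This module
partitions the citations bearing one name key into inferred identities by a
greedy loop: repeatedly find the most frequent coauthor among the remaining
citations, peel off the citations that include that coauthor as one profile
anchored to it, and continue on the remainder until no coauthor recurs.
Leftover citations become singleton profiles.

The procedure is deliberately conservative: one real person who publishes
with two disjoint collaborator groups is split into two profiles
(atomization — high precision, low recall), which is acceptable when the
goal is finding experts in narrow areas.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

from .records_io import Citation, CitationCorpus

__all__ = [
    "DisambiguatedAuthor",
    "coauthor_frequencies",
    "disambiguate_name",
    "disambiguate_corpus",
    "write_authors_tsv",
    "read_authors_tsv",
]

_ORDINAL_WIDTH = 4


@dataclass(frozen=True)
class DisambiguatedAuthor:
    """One inferred author identity.

    ``anchor_coauthor`` is the recurring coauthor whose presence defines the
    profile's citation subset; it is ``None`` exactly for singletons.
    """

    author_id: str
    name_key: str
    anchor_coauthor: str | None
    pmids: frozenset[str]

    @property
    def is_singleton(self) -> bool:
        return self.anchor_coauthor is None

    @property
    def n_refs(self) -> int:
        return len(self.pmids)


def coauthor_frequencies(name_key: str, citations: Iterable[Citation]) -> dict[str, int]:
    """Count, for each other name key, the citations where it co-occurs with
    ``name_key``. A coauthor key counts at most once per citation; the name
    itself is excluded."""
    counts: Counter[str] = Counter()
    for cit in citations:
        keys = set(cit.author_keys)
        if name_key not in keys:
            raise ValueError(f"citation {cit.pmid} does not list {name_key!r}")
        counts.update(keys - {name_key})
    return dict(counts)


def _make_id(name_key: str, ordinal: int) -> str:
    return f"{name_key}#{ordinal:0{_ORDINAL_WIDTH}d}"


def disambiguate_name(
    name_key: str,
    corpus: CitationCorpus,
    min_repeat: int = 2,
    drop_single_author: bool = False,
) -> list[DisambiguatedAuthor]:
    """Partition the citations bearing ``name_key`` into identities.

    Greedy loop: while the most frequent coauthor over the *remaining*
    citations recurs at least ``min_repeat`` times, emit a profile holding
    exactly the remaining citations that include it, anchored to it, and
    remove them. Ties between equally frequent coauthors break
    lexicographically. Every leftover citation then becomes its own
    singleton profile (ordered by pmid). The result is a partition of the
    name's citations, invariant to corpus record order.

    ``drop_single_author=True`` excludes single-author citations entirely
    instead of emitting them as singletons.
    """
    index = corpus.name_index
    if name_key not in index:
        raise KeyError(f"name key {name_key!r} not in corpus")
    remaining = {pmid: corpus.get(pmid) for pmid in index[name_key]}
    if drop_single_author:
        remaining = {p: c for p, c in remaining.items() if len(set(c.author_keys)) > 1}

    profiles: list[DisambiguatedAuthor] = []
    ordinal = 1
    while remaining:
        freqs = coauthor_frequencies(name_key, remaining.values())
        if not freqs:
            break
        best_count = max(freqs.values())
        if best_count < min_repeat:
            break
        anchor = min(k for k, c in freqs.items() if c == best_count)
        member_pmids = frozenset(
            p for p, c in remaining.items() if anchor in set(c.author_keys)
        )
        profiles.append(
            DisambiguatedAuthor(
                author_id=_make_id(name_key, ordinal),
                name_key=name_key,
                anchor_coauthor=anchor,
                pmids=member_pmids,
            )
        )
        ordinal += 1
        for pmid in member_pmids:
            del remaining[pmid]

    for pmid in sorted(remaining):
        profiles.append(
            DisambiguatedAuthor(
                author_id=_make_id(name_key, ordinal),
                name_key=name_key,
                anchor_coauthor=None,
                pmids=frozenset({pmid}),
            )
        )
        ordinal += 1
    return profiles


def disambiguate_corpus(
    corpus: CitationCorpus,
    min_repeat: int = 2,
    drop_single_author: bool = False,
) -> dict[str, list[DisambiguatedAuthor]]:
    """Apply :func:`disambiguate_name` independently to every name key.

    Output is a pure function of the citation multiset: keys are processed
    in sorted order and each name's partition is itself deterministic.
    """
    return {
        key: disambiguate_name(key, corpus, min_repeat=min_repeat,
                               drop_single_author=drop_single_author)
        for key in sorted(corpus.name_index)
    }


def write_authors_tsv(
    partitions: Mapping[str, list[DisambiguatedAuthor]], stream: IO[str]
) -> None:
    stream.write("author_id\tname_key\tanchor_coauthor\tn_refs\tpmids\n")
    for key in sorted(partitions):
        for author in partitions[key]:
            stream.write(
                "\t".join(
                    [
                        author.author_id,
                        author.name_key,
                        author.anchor_coauthor or "-",
                        str(author.n_refs),
                        ",".join(sorted(author.pmids)),
                    ]
                )
                + "\n"
            )


def read_authors_tsv(stream: IO[str]) -> dict[str, list[DisambiguatedAuthor]]:
    partitions: dict[str, list[DisambiguatedAuthor]] = {}
    header = next(stream, None)
    if header is None:
        return partitions
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        author_id, name_key, anchor, _n, pmids = line.split("\t")
        partitions.setdefault(name_key, []).append(
            DisambiguatedAuthor(
                author_id=author_id,
                name_key=name_key,
                anchor_coauthor=None if anchor == "-" else anchor,
                pmids=frozenset(pmids.split(",")),
            )
        )
    return partitions
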