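"""Reading, validation and normalization of citation corpora.

Two input dialects are supported:

* the MEDLINE flat-file dialect (``PMID- ``/``TI  - ``/``AB  - ``/``AU  - ``/
  ``JT  - ``/``DP  - `` tags, continuation lines indented), and
* a line-delimited JSON fixture dialect (one object per line with keys
  ``pmid``, ``title``, ``abstract``, ``authors``, ``journal_id``, ``year``).

Author names are normalized into the ``lastname_initials`` key space used
throughout the pipeline: many distinct people can share one key, which is
precisely the ambiguity the disambiguation stage resolves.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "AuthorName",
    "Citation",
    "CitationCorpus",
    "MalformedRecordError",
    "DuplicatePmidError",
    "normalize_name",
    "parse_medline",
    "write_jsonl",
]


class MalformedRecordError(ValueError):
    """A record or author string that cannot be interpreted."""


class DuplicatePmidError(ValueError):
    """Two records in one corpus share a PMID."""


@dataclass(frozen=True, order=True)
class AuthorName:
    """A normalized author mention: lower-cased, diacritic-folded.

    ``last_name`` keeps internal hyphens/apostrophes/spaces; ``initials`` may
    be empty (collective or group authors).
    """

    last_name: str
    initials: str

    @property
    def name_key(self) -> str:
        return f"{self.last_name}_{self.initials}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name_key


def _fold(text: str) -> str:
    """Lower-case and strip combining marks, keeping base letters."""
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(c for c in decomposed if not unicodedata.combining(c)).lower()


# A trailing token is taken as the initials block only when it looks like
# MEDLINE initials: all-alphabetic, all-uppercase, short.  This keeps
# collective entries such as "the FANTOM Consortium" intact with empty
# initials instead of mistaking "Consortium" for initials.
_MAX_INITIALS = 3


def normalize_name(raw: str) -> AuthorName:
    """Normalize a raw author string into an :class:`AuthorName`.

    Accepts the MEDLINE rendering (``"Andrade-Navarro MA"``) and the
    already-normalized key rendering (``"andrade-navarro_ma"``); the latter
    round-trips to the same key (idempotence). Diacritics are folded to base
    letters; hyphens and apostrophes inside last names are preserved.
    Suffix-like trailing tokens that do not look like initials stay inside
    the last-name token as-is.

    Raises
    ------
    MalformedRecordError
        If the input is empty or whitespace-only.
    """
    if raw is None or not raw.strip():
        raise MalformedRecordError("empty author string")
    raw = raw.strip()

    # MEDLINE raw strings never contain underscores, so one marks the
    # already-normalized key rendering (even for spaced last names).
    if "_" in raw:
        last, _, initials = raw.rpartition("_")
        if not last:
            raise MalformedRecordError(f"malformed name key: {raw!r}")
        return AuthorName(last_name=_fold(last), initials=_fold(initials))

    tokens = raw.split()
    if len(tokens) >= 2 and tokens[-1].isalpha() and tokens[-1].isupper() and len(tokens[-1]) <= _MAX_INITIALS:
        last = " ".join(tokens[:-1])
        initials = tokens[-1]
    else:
        last = " ".join(tokens)
        initials = ""
    folded_last = _fold(last)
    if not folded_last:
        raise MalformedRecordError(f"no last name in author string: {raw!r}")
    return AuthorName(last_name=folded_last, initials=_fold(initials))


@dataclass(frozen=True)
class Citation:
    """One bibliographic record.

    ``authors`` preserves source order — first/last positions carry meaning
    for profile eligibility.
    """

    pmid: str
    title: str
    abstract: str
    authors: tuple[AuthorName, ...]
    journal_id: str
    year: int

    def __post_init__(self) -> None:
        if not self.pmid:
            raise MalformedRecordError("citation without pmid")
        if not self.authors:
            raise MalformedRecordError(f"citation {self.pmid} has no authors")

    @property
    def author_keys(self) -> tuple[str, ...]:
        return tuple(a.name_key for a in self.authors)


@dataclass
class CitationCorpus:
    """A set of citations plus the inverted name index."""

    _by_pmid: dict[str, Citation] = field(default_factory=dict)

    def add(self, citation: Citation) -> None:
        if citation.pmid in self._by_pmid:
            raise DuplicatePmidError(f"duplicate PMID {citation.pmid}")
        self._by_pmid[citation.pmid] = citation

    def __len__(self) -> int:
        return len(self._by_pmid)

    def __iter__(self) -> Iterator[Citation]:
        return iter(self._by_pmid.values())

    def __contains__(self, pmid: str) -> bool:
        return pmid in self._by_pmid

    def get(self, pmid: str) -> Citation:
        try:
            return self._by_pmid[pmid]
        except KeyError:
            raise KeyError(f"unknown pmid {pmid!r}") from None

    @property
    def name_index(self) -> dict[str, set[str]]:
        """Inverted map ``name_key -> set of pmids`` (rebuilt on access)."""
        index: dict[str, set[str]] = {}
        for cit in self._by_pmid.values():
            for key in set(cit.author_keys):
                index.setdefault(key, set()).add(cit.pmid)
        return index

    @classmethod
    def from_citations(cls, citations: Iterable[Citation]) -> "CitationCorpus":
        corpus = cls()
        for cit in citations:
            corpus.add(cit)
        return corpus

    def summary(self) -> str:
        return f"{len(self)} citations, {len(self.name_index)} distinct name keys"


_YEAR_RE = re.compile(r"(\d{4})")
_TAG_RE = re.compile(r"^([A-Z][A-Z0-9]{1,3})\s*- (.*)$")


def _extract_year(date_field: str) -> int | None:
    m = _YEAR_RE.search(date_field)
    return int(m.group(1)) if m else None


def _flat_records(lines: Iterable[str]) -> Iterator[list[tuple[str, str]]]:
    """Group flat-file lines into records of (tag, joined value) pairs."""
    fields: list[tuple[str, str]] = []
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip():
            if fields:
                yield fields
                fields = []
            continue
        m = _TAG_RE.match(line)
        if m:
            fields.append((m.group(1), m.group(2).strip()))
        elif line[:1].isspace() and fields:
            # continuation line: joined with a single space
            tag, value = fields[-1]
            fields[-1] = (tag, f"{value} {line.strip()}")
        # anything else is noise between records; ignored
    if fields:
        yield fields


def _citation_from_flat(fields: list[tuple[str, str]]) -> Citation | None:
    pmid = title = abstract = journal = date = ""
    authors: list[AuthorName] = []
    for tag, value in fields:
        if tag == "PMID" and not pmid:
            pmid = value
        elif tag == "TI":
            title = value
        elif tag == "AB":
            abstract = value
        elif tag == "AU":
            authors.append(normalize_name(value))
        elif tag in ("JT", "TA") and not journal:
            journal = value
        elif tag == "DP":
            date = value
    if not pmid or not authors:
        logger.warning("skipping record without PMID or authors (pmid=%r)", pmid or None)
        return None
    year = _extract_year(date)
    if year is None:
        logger.warning("skipping record %s: no 4-digit year in DP field %r", pmid, date)
        return None
    return Citation(pmid=pmid, title=title, abstract=abstract,
                    authors=tuple(authors), journal_id=journal, year=year)


def _citation_from_json(obj: dict) -> Citation | None:
    pmid = str(obj.get("pmid") or "")
    raw_authors = obj.get("authors") or []
    if not pmid or not raw_authors:
        logger.warning("skipping JSON record without pmid or authors (pmid=%r)", pmid or None)
        return None
    return Citation(
        pmid=pmid,
        title=obj.get("title", ""),
        abstract=obj.get("abstract", ""),
        authors=tuple(normalize_name(a) for a in raw_authors),
        journal_id=str(obj.get("journal_id", "")),
        year=int(obj["year"]),
    )


def parse_medline(stream: IO[str] | Iterable[str], dialect: str = "medline") -> CitationCorpus:
    """Parse a citation corpus from ``stream``.

    Parameters
    ----------
    stream:
        Text stream or iterable of lines in the declared dialect.
    dialect:
        ``"medline"`` for the flat-file dialect, ``"jsonl"`` for the
        line-delimited JSON fixture dialect.

    Records missing a PMID or an author list are skipped with a logged
    warning; a duplicate PMID raises :class:`DuplicatePmidError`.
    """
    corpus = CitationCorpus()
    skipped = 0
    if dialect == "medline":
        for fields in _flat_records(stream):
            cit = _citation_from_flat(fields)
            if cit is None:
                skipped += 1
            else:
                corpus.add(cit)
    elif dialect == "jsonl":
        for line in stream:
            if not line.strip():
                continue
            cit = _citation_from_json(json.loads(line))
            if cit is None:
                skipped += 1
            else:
                corpus.add(cit)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    logger.info("parsed corpus: %s (%d records skipped)", corpus.summary(), skipped)
    return corpus


def write_jsonl(corpus: CitationCorpus, stream: IO[str]) -> None:
    """Write the corpus in the fixture dialect; round-trips via parse_medline."""
    for cit in corpus:
        obj = {
            "pmid": cit.pmid,
            "title": cit.title,
            "abstract": cit.abstract,
            "authors": [a.name_key for a in cit.authors],
            "journal_id": cit.journal_id,
            "year": cit.year,
        }
        stream.write(json.dumps(obj, ensure_ascii=False) + "\n")
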