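"""Synthetic citation corpora with known ground truth.

Real MEDLINE cannot be bundled, and the disambiguation problem only needs
its *structure*: distinct scientist identities that may share a
``lastname_initials`` key, each publishing repeatedly with a private clique
of collaborators, on a topic with its own vocabulary. The generator emits
exactly that structure so every pipeline stage can be tested against known
truth:

* identities colliding on a name key in pairs, at a configurable rate;
* per-identity coauthor cliques, pairwise disjoint in separable mode, with
  one dedicated clique member present on every paper (so the greedy
  coauthor loop can recover identities perfectly);
* abstracts as bag-of-words sentences drawn from the identity's topic
  vocabulary mixed with a shared background vocabulary — no grammar, since
  downstream stages only use sentence co-occurrence and term frequencies;
* a split-clique scenario where one identity publishes with two disjoint
  recurring collaborator groups, the canonical atomization case.

Corpora are byte-reproducible given the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import IO

import yaml

from .records_io import AuthorName, Citation, CitationCorpus

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate",
    "split_clique_scenario",
    "write_truth_tsv",
    "read_truth_tsv",
]

_SYLLABLES = [
    "an", "bar", "chen", "dor", "el", "fa", "gri", "hol", "iv", "jan",
    "kor", "lem", "mor", "nov", "os", "pet", "qui", "ros", "sol", "tan",
    "ur", "vas", "wol", "yam", "zel",
]
_INITIALS = "abcdefghijklmnopqrstuvwxyz"

_DEFAULT_SUBJECT_POOL = [
    "Cardiology", "Genetics", "Neurology", "Oncology", "Immunology",
    "Microbiology",
]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus.

    Defaults describe a small but structurally faithful corpus: 50 target
    identities, every one colliding pairwise on a shared name key, about
    five papers each over 1998-2012 (so the 2000-2010 eligibility window is
    a strict subset), three disjoint 40-word topic vocabularies over a
    shared background vocabulary.
    """

    n_identities: int = 50
    name_collision_rate: float = 1.0
    papers_per_identity: tuple[int, int] = (5, 5)
    coauthors_per_identity: tuple[int, int] = (2, 4)
    n_topics: int = 3
    topic_vocab_size: int = 40
    topic_overlap: float = 0.0
    background_vocab_size: int = 30
    background_weight: float = 0.25
    sentences_per_abstract: tuple[int, int] = (3, 6)
    words_per_sentence: tuple[int, int] = (6, 12)
    year_range: tuple[int, int] = (1998, 2012)
    n_journals: int = 8
    subject_pool: list[str] = field(default_factory=lambda: list(_DEFAULT_SUBJECT_POOL))
    separable: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("papers_per_identity", "coauthors_per_identity",
                     "sentences_per_abstract", "words_per_sentence", "year_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 and name != "year_range":
                raise ValueError(f"{name} must be positive")
            if hi < lo:
                raise ValueError(f"{name} range inverted")
        if not 0.0 <= self.name_collision_rate <= 1.0:
            raise ValueError("name_collision_rate must be in [0, 1]")

    @classmethod
    def from_yaml(cls, stream: IO[str]) -> "GeneratorConfig":
        data = yaml.safe_load(stream) or {}
        for key in ("papers_per_identity", "coauthors_per_identity",
                    "sentences_per_abstract", "words_per_sentence", "year_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def journal_pool(self) -> list[str]:
        return [f"J{j:02d}" for j in range(1, self.n_journals + 1)]

    def subject_map(self) -> dict[str, set[str]]:
        """Deterministic journal -> subject assignment (cycled)."""
        return {
            journal: {self.subject_pool[j % len(self.subject_pool)]}
            for j, journal in enumerate(self.journal_pool())
        }


GroundTruth = dict  # (pmid, name_key) -> identity_id


def _fresh_names(rng: random.Random, n: int, used: set[str]) -> list[AuthorName]:
    """Generate n distinct author names whose keys are new to `used`."""
    names: list[AuthorName] = []
    attempts = 0
    while len(names) < n:
        attempts += 1
        if attempts > 100 * n + 1000:
            raise ValueError("name pool exhausted: config requests more distinct names than available")
        last = "".join(rng.choice(_SYLLABLES) for _ in range(rng.randint(2, 3)))
        initials = rng.choice(_INITIALS)
        name = AuthorName(last_name=last, initials=initials)
        if name.name_key in used:
            continue
        used.add(name.name_key)
        names.append(name)
    return names


def _topic_vocabularies(rng: random.Random, config: GeneratorConfig) -> tuple[list[list[str]], list[str]]:
    """Topic vocabularies (optionally overlapping via a shared pool) plus a
    background vocabulary disjoint from every topic."""
    n_shared = int(round(config.topic_overlap * config.topic_vocab_size))
    shared = [f"sharedterm{rng.randrange(10**6):06d}" for _ in range(n_shared)]
    topics = []
    for t in range(config.n_topics):
        own = [f"topic{t}term{w:03d}" for w in range(config.topic_vocab_size - n_shared)]
        topics.append(own + shared)
    background = [f"methodterm{w:03d}" for w in range(config.background_vocab_size)]
    return topics, background


def _abstract(rng: random.Random, vocab: list[str], background: list[str],
              config: GeneratorConfig) -> str:
    sentences = []
    for _ in range(rng.randint(*config.sentences_per_abstract)):
        words = []
        for _ in range(rng.randint(*config.words_per_sentence)):
            pool = background if rng.random() < config.background_weight else vocab
            words.append(rng.choice(pool))
        words[0] = words[0].capitalize()  # sentence-split heuristic needs a case boundary
        sentences.append(" ".join(words) + ".")
    return " ".join(sentences)


def generate(config: GeneratorConfig) -> tuple[CitationCorpus, GroundTruth]:
    """Generate a corpus plus ground-truth identity labels.

    Every target identity gets a name key (shared pairwise with another
    identity per ``name_collision_rate``), a coauthor clique disjoint from
    all other cliques in separable mode, and a topic. Each paper lists the
    identity first, its dedicated recurring coauthor (clique member 0), and
    a random sample of further clique members. Truth labels every
    (pmid, name_key) authorship of the target identities.
    """
    rng = random.Random(config.seed)
    used_keys: set[str] = set()
    n = config.n_identities

    n_colliding = int(round(config.name_collision_rate * n))
    n_colliding -= n_colliding % 2  # collisions come in pairs
    n_keys = (n - n_colliding) + n_colliding // 2
    key_names = _fresh_names(rng, n_keys, used_keys)
    # first n_colliding identities share keys pairwise
    identity_names: list[AuthorName] = []
    for i in range(n_colliding):
        identity_names.append(key_names[i // 2])
    identity_names.extend(key_names[n_colliding // 2: n_keys])

    topics, background = _topic_vocabularies(rng, config)
    journals = config.journal_pool()

    corpus = CitationCorpus()
    truth: GroundTruth = {}
    pmid_counter = 1
    for ident in range(n):
        identity_id = f"I{ident + 1:04d}"
        name = identity_names[ident]
        clique_size = rng.randint(*config.coauthors_per_identity)
        if config.separable:
            clique = _fresh_names(rng, clique_size, used_keys)
        else:
            clique = _fresh_names(rng, clique_size, set())
        vocab = topics[ident % len(topics)]
        for _ in range(rng.randint(*config.papers_per_identity)):
            extras = rng.sample(clique[1:], rng.randint(0, len(clique) - 1))
            authors = (name, clique[0], *extras)
            pmid = str(1000000 + pmid_counter)
            pmid_counter += 1
            cit = Citation(
                pmid=pmid,
                title=" ".join(rng.choice(vocab) for _ in range(4)).capitalize(),
                abstract=_abstract(rng, vocab, background, config),
                authors=authors,
                journal_id=rng.choice(journals),
                year=rng.randint(*config.year_range),
            )
            corpus.add(cit)
            truth[(pmid, name.name_key)] = identity_id
    return corpus, truth


def split_clique_scenario(
    config: GeneratorConfig | None = None,
    papers_per_group: int = 3,
    merged: bool = False,
) -> tuple[CitationCorpus, GroundTruth]:
    """One identity, two disjoint recurring collaborator groups.

    The identity publishes ``papers_per_group`` papers with each group;
    truth labels all papers as one identity. The greedy coauthor loop
    splits them into two profiles (atomization) unless ``merged=True``, in
    which case both groups collapse into one clique present on every paper
    and a single profile is expected.
    """
    config = config or GeneratorConfig()
    rng = random.Random(config.seed)
    used: set[str] = set()
    (name,) = _fresh_names(rng, 1, used)
    group_a, group_b = _fresh_names(rng, 2, used)
    topics, background = _topic_vocabularies(rng, config)
    journals = config.journal_pool()

    corpus = CitationCorpus()
    truth: GroundTruth = {}
    for group_idx, recurring in enumerate((group_a, group_b)):
        for p in range(papers_per_group):
            if merged:
                coauthors = [group_a, group_b]
            else:
                # one-off extra coauthor keeps records multi-author but non-recurring
                coauthors = [recurring] + _fresh_names(rng, 1, used)
            pmid = str(2000000 + group_idx * papers_per_group + p + 1)
            cit = Citation(
                pmid=pmid,
                title="Synthetic split-clique record",
                abstract=_abstract(rng, topics[group_idx % len(topics)], background, config),
                authors=(name, *coauthors),
                journal_id=rng.choice(journals),
                year=rng.randint(*config.year_range),
            )
            corpus.add(cit)
            truth[(pmid, name.name_key)] = "I0001"
    return corpus, truth


def write_truth_tsv(truth: GroundTruth, stream: IO[str]) -> None:
    stream.write("pmid\tname_key\tidentity_id\n")
    for (pmid, key), identity in sorted(truth.items()):
        stream.write(f"{pmid}\t{key}\t{identity}\n")


def read_truth_tsv(stream: IO[str]) -> GroundTruth:
    truth: GroundTruth = {}
    header = next(stream, None)
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        pmid, key, identity = line.split("\t")
        truth[(pmid, key)] = identity
    return truth
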