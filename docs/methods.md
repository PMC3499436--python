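# Methods

## Problem and model

`peerfind` recommends peer reviewers for a manuscript given only a citation
corpus and the manuscript's abstract. The underlying model has three parts:
a clustering model of author identity, a graded word-association model for
query keywords, and a vector-space retrieval model over per-identity term
profiles. Each is intentionally simple and fully deterministic.

### Author-name disambiguation

An author *mention* is reduced to a name key `lastname_initials`
(lower-cased, diacritics folded to base letters, hyphens and apostrophes
preserved). The working assumption is that one scientist publishes
repeatedly with the same collaborators, while two different scientists who
happen to share a name key rarely share coauthors. For one name key the
algorithm is a greedy loop over its citation set:

1. count, over the remaining citations, how many list each other name key
   as coauthor (at most once per citation);
2. if the maximum count is at least `min_repeat` (default 2), emit one
   identity containing exactly the remaining citations that include that
   most frequent coauthor — the identity's *anchor* — and remove them;
3. otherwise stop; every leftover citation becomes a singleton identity.

Frequencies are re-counted over the remainder at each step (step 1), so the
anchor of each successive identity has, at its extraction time, frequency
no larger than its predecessor's. Ties between equally frequent coauthors
break lexicographically on the name key; this, plus pmid-sorted singleton
emission, makes the partition a pure function of the citation multiset
(order invariance is tested by shuffling). Identity ids are
`name_key#NNNN` with a zero-padded extraction ordinal.

Known behaviour, not a defect: a scientist with two disjoint recurring
collaborator groups is split into two identities (*atomization*). The
partition therefore has high pairwise precision and low recall; for expert
finding in narrow fields the split profiles are still individually
coherent. Single-author citations carry no coauthor signal; they are kept
as singletons by default, and a `drop_single_author` flag discards them for
builds that only want multi-author evidence.

### Keyword scoring

Query text is split into sentences (terminal `.!?` + whitespace, with a
configurable abbreviation list and an upper-case/digit boundary heuristic),
lower-cased, tokenized, and stop-word filtered. A part-of-speech tagger is
an injectable interface: when present, only nouns/adjectives/verbs survive
on the query side and nouns on the profile side; the default *null tagger*
applies stop-word filtering alone, with the same contract on both sides so
query and profile vocabularies stay symmetric. The shipped stop-word list
(155 English function words) can be replaced by a one-token-per-line file.

Word association is a fuzzy binary relation over sentence co-occurrence:
with `s(i)` the number of sentences containing term *i* and `s(i,j)` the
number containing both,

    mu(i,j) = s(i,j)^2 / (s(i) * s(j))  in [0,1],

which is 1 exactly when *i* and *j* always co-occur and 0 when they never
do, and is invariant under duplicating the whole text. A term's raw score
is the sum of its relations; scores are normalized by the maximum so the
best-connected term scores 1. The query profile keeps at most `max_terms`
(default 50) terms with score **strictly** above `min_score` (default
0.05). Empty or too-short text yields an empty profile; the search layer
turns that into an explicit "no keywords" error rather than returning an
arbitrary ranking.

### Expert profiles and retrieval

An identity is *eligible* for indexing when at least one attributed
citation has it as first or last author (single-author papers count as
both), with year in `[year_min, year_max]` (default 2000–2010, inclusive)
and, when a journal list is supplied, in a listed journal. Eligible
identities get a term-frequency vector over their attributed abstracts
(counts, not presence/absence — richer and reduces ties); abstract-free
citations still contribute journals and years. Profiles whose abstracts are
all empty are flagged unindexable and skipped.

Ranking uses a classic practical TF-IDF similarity: for query q with
keyword weights `w_q(t)` and profile d,

    idf(t)   = max(1 + ln(N / (df(t) + 1)), 1e-6)
    score    = (|overlap| / |q|) * sum_t w_q(t) * idf(t)^2 * sqrt(tf(t,d)) / sqrt(|d|)

The 1e-6 floor prevents negative idf for terms present in most profiles of
a tiny corpus; scores are therefore non-negative and zero exactly when
query and profile share no term. Subject filtering is a *post-filter*: it
restricts the candidate set to authors with at least one citation in a
journal mapped to a selected broad subject, but idf stays computed over the
full index, so a surviving author's score is unchanged by the filter. Each
hit is displayed with its ten highest tf·idf profile terms and its anchor
coauthor (itself a plausible alternative suggestion). Scores are not
normalized per query; they are comparable within one result list, not
across queries.

## Synthetic corpora

The generator emulates exactly the structure the method exploits, with
ground-truth identity labels:

* `n_identities` scientist identities (default 50), colliding pairwise on a
  shared name key at `name_collision_rate` (default 1.0, i.e. 25 shared
  keys — the hardest setting for disambiguation);
* each identity has a private coauthor clique (2–4 members, disjoint from
  all other cliques in `separable` mode) whose first member co-signs every
  one of the identity's papers (default 5) — the condition under which the
  greedy loop can recover identities exactly;
* abstracts are bag-of-words sentences (3–6 sentences of 6–12 words) drawn
  from the identity's topic vocabulary (3 disjoint 40-word vocabularies by
  default, overlap configurable) mixed with a shared 30-word background
  vocabulary at weight 0.25 — no grammar, since downstream stages use only
  sentence co-occurrence and term frequencies;
* years span 1998–2012 so the 2000–2010 eligibility window selects a strict
  subset; 8 journals carry cycled broad-subject labels.

The `split_clique_scenario` builds the canonical atomization case: one
identity, two disjoint recurring collaborators, 3+3 papers (plus one-off
coauthors so records stay multi-author); its `merged` variant puts both
recurring collaborators on every paper as a control that yields one
profile. All generation is driven by one `random.Random(seed)` stream and
is byte-reproducible.

What the generator does **not** emulate — and hence what passing tests do
not establish about real literature: realistic name-frequency and
collision distributions, collaboration-network topology, partially
overlapping cliques between true namesakes, grammatical sentence structure,
vocabulary drift over time, and noisy or incomplete records. Results on
synthetic corpora certify the algorithmic contracts (partition invariants,
exact recovery under separability, score definitions), not field accuracy.

## Evaluation

Disambiguation accuracy is pairwise precision/recall over same-name
authorship pairs: precision = co-clustered pairs that are truly the same
identity / all co-clustered pairs; recall = the same numerator / all truly
co-identical pairs; F1 is their harmonic mean. An undefined denominator
(e.g. all-singleton predictions) reports the metric as 1.0 with an explicit
`*_vacuous` flag. On the 3+3 split-clique case the expected values are
precision 1.0 and recall 6/15 = 0.4 (each group contributes C(3,2) = 3
correct pairs of the C(6,2) = 15 true pairs).

The cited-author benchmark checks whether the top suggested expert for a
manuscript authored one of its cited references, skipping suggestions whose
name key is an author of the manuscript itself; the first non-self
suggestion is the one evaluated. Matching is by exact normalized name key
(the manual-judgment variant of this check is out of scope).

## Numerical and design choices

* **Relation formula.** The co-occurrence relation above is this package's
  fully specified choice of a fuzzy binary relation; it is monotone in
  joint occurrences, bounded, and cheap to compute exactly, and the test
  suite pins it against an independent brute-force enumeration to 1e-12.
* **Retrieval formula.** The TF-IDF variant (sqrt tf, squared idf,
  inverse-sqrt length norm, coordination factor) is the classic practical
  scoring of early Lucene-style engines, re-implemented natively and pinned
  against a brute-force scorer to 1e-9.
* **Tie-breaks.** Coauthor ties: lexicographic; result ties: author id;
  keyword ties: term lexicographic. All chosen for determinism.
* **Problem sizes.** Tests and the acceptance script run on corpora of
  50–250 citations and indexes of up to ~150 profiles, sizes at which every
  quantity can be cross-checked by exhaustive enumeration; the algorithms
  themselves are linear to near-linear in corpus size per name key.
* **Degenerate inputs.** Empty streams parse to empty corpora; empty text
  yields an empty keyword profile; an empty profile store refuses to build
  an index; an all-self result list reports no evaluable suggestion.

## Limitations

Name keys ignore affiliation, full given names and subject signals, so two
namesakes sharing a frequent collaborator merge, and one scientist's work
fragments across collaborator groups (recall loss by design). The null
tagger keeps all non-stop content words rather than nouns only, a
documented divergence applied symmetrically on both sides of the match.
Sentence splitting is heuristic and English-oriented. Retrieval scores are
corpus-dependent and not calibrated probabilities.
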