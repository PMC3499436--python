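"""Inverted index construction and TF-IDF expert ranking."""

import io
import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peerfind.expert_index import (
    EmptyStoreError,
    NoKeywordsError,
    build_index,
    journal_table,
    read_subject_map,
    score_expert,
    search,
)
from peerfind.keyword_extraction import KeywordProfile
from peerfind.profiles import ExpertProfile
from oracles import brute_force_retrieval_score


def _profile(author_id, term_counts, journals=("J01",), anchor="x_y"):
    return ExpertProfile(
        author_id=author_id,
        term_counts=dict(term_counts),
        n_abstracts=1,
        journals=frozenset(journals),
        years=frozenset({2005}),
        anchor_coauthor=anchor,
        n_refs=len(term_counts) or 1,
    )


def _query(weights):
    entries = tuple(sorted(weights.items(), key=lambda ts: (-ts[1], ts[0])))
    return KeywordProfile(entries=entries)


def test_build_index_doc_freq_and_counts():
    store = [
        _profile("a#1", {"kinase": 2, "cycle": 1}),
        _profile("b#1", {"kinase": 5}),
        _profile("c#1", {"membrane": 3}),
    ]
    idx = build_index(store)
    assert idx.n_docs == 3
    assert idx.doc_freq["kinase"] == 2
    assert idx.doc_len == {"a#1": 3, "b#1": 5, "c#1": 3}
    assert idx.postings["kinase"] == [("a#1", 2), ("b#1", 5)]


def test_empty_store_raises():
    with pytest.raises(EmptyStoreError):
        build_index([])


def test_duplicate_author_id_raises():
    store = [_profile("a#1", {"x": 1}), _profile("a#1", {"y": 1})]
    with pytest.raises(ValueError):
        build_index(store)


def test_index_invariant_under_store_order():
    store = [
        _profile("a#1", {"kinase": 2}),
        _profile("b#1", {"kinase": 5, "cycle": 1}),
        _profile("c#1", {"membrane": 3}),
    ]
    idx1 = build_index(store)
    idx2 = build_index(list(reversed(store)))
    assert idx1.doc_freq == idx2.doc_freq
    assert idx1.postings == idx2.postings


def test_score_zero_without_overlap():
    idx = build_index([_profile("a#1", {"kinase": 2})])
    assert score_expert(_query({"membrane": 1.0}), "a#1", idx) == 0.0


def test_score_single_term_closed_form():
    # one doc, tf=4, doc_len=4: score = (1 + ln 1/2)^2
    idx = build_index([_profile("a#1", {"kinase": 4})])
    expected = (1.0 + math.log(0.5)) ** 2
    assert score_expert(_query({"kinase": 1.0}), "a#1", idx) == pytest.approx(expected)


def test_score_increases_with_tf():
    low = build_index([_profile("a#1", {"kinase": 2, "pad": 6})])
    high = build_index([_profile("a#1", {"kinase": 4, "pad": 4})])
    q = _query({"kinase": 1.0})
    assert score_expert(q, "a#1", high) > score_expert(q, "a#1", low)


def test_unknown_author_raises():
    idx = build_index([_profile("a#1", {"x": 1})])
    with pytest.raises(KeyError):
        score_expert(_query({"x": 1.0}), "zzz#1", idx)


def test_search_empty_query_raises():
    store = {"a#1": _profile("a#1", {"x": 1})}
    idx = build_index(store.values())
    with pytest.raises(NoKeywordsError):
        search(KeywordProfile(entries=()), idx, store)


def test_subject_filter_removes_without_rescoring():
    store = {
        "a#1": _profile("a#1", {"kinase": 4}, journals=("J01",)),
        "b#1": _profile("b#1", {"kinase": 2}, journals=("J02",)),
    }
    idx = build_index(store.values())
    subject_map = {"J01": {"Cardiology"}, "J02": {"Genetics"}}
    q = _query({"kinase": 1.0})
    unfiltered = search(q, idx, store)
    filtered = search(q, idx, store, subjects=["Genetics"], subject_map=subject_map)
    assert [h.author_id for h in filtered] == ["b#1"]
    unfiltered_scores = {h.author_id: h.score for h in unfiltered}
    for hit in filtered:
        assert hit.score == unfiltered_scores[hit.author_id]


def test_search_without_subjects_ranks_all():
    store = {
        "a#1": _profile("a#1", {"kinase": 9, "other": 7}),
        "b#1": _profile("b#1", {"kinase": 1, "other": 15}),
        "c#1": _profile("c#1", {"membrane": 1}),
    }
    idx = build_index(store.values())
    hits = search(_query({"kinase": 1.0}), idx, store, top_k=3)
    assert [h.author_id for h in hits] == ["a#1", "b#1", "c#1"]
    assert hits[0].score > hits[1].score > hits[2].score == 0.0


def test_display_keywords_come_from_profile():
    store = {"a#1": _profile("a#1", {f"t{i}": i + 1 for i in range(15)})}
    idx = build_index(store.values())
    hits = search(_query({"t14": 1.0}), idx, store)
    assert len(hits[0].display_keywords) == 10
    assert "t14" in hits[0].display_keywords


def test_journal_table_counts_distinct_experts():
    store = {
        "a#1": _profile("a#1", {"x": 1}, journals=("J01", "J02")),
        "b#1": _profile("b#1", {"x": 1}, journals=("J02",)),
    }
    idx = build_index(store.values())
    hits = search(_query({"x": 1.0}), idx, store)
    table = journal_table(hits, store)
    assert table == [("J02", 2), ("J01", 1)]
    assert sum(c for _, c in table) >= len(hits)


def test_read_subject_map():
    stream = io.StringIO("J01\tCardiology\nJ01\tGenetics\nJ02\tGenetics\n")
    assert read_subject_map(stream) == {
        "J01": {"Cardiology", "Genetics"},
        "J02": {"Genetics"},
    }


_terms = [f"t{i}" for i in range(30)]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10**9))
def test_ranked_scores_match_brute_force_oracle(seed):
    rng = random.Random(seed)
    n_profiles = rng.randint(1, 20)
    store = {}
    for i in range(n_profiles):
        vocab = rng.sample(_terms, rng.randint(1, 8))
        store[f"p{i}#1"] = _profile(
            f"p{i}#1", {t: rng.randint(1, 9) for t in vocab}
        )
    idx = build_index(store.values())
    weights = {t: rng.random() for t in rng.sample(_terms, rng.randint(1, 6))}
    q = _query(weights)
    counts = [p.term_counts for p in store.values()]
    for aid, profile in store.items():
        ours = score_expert(q, aid, idx)
        oracle = brute_force_retrieval_score(weights, profile.term_counts, counts)
        assert ours == pytest.approx(oracle, abs=1e-9)
        assert ours >= 0.0
        overlap = set(weights) & {t for t, c in profile.term_counts.items() if c}
        assert (ours == 0.0) == (not overlap)
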