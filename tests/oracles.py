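"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: they recompute keyword
scores and retrieval scores directly from definitions, by explicit
enumeration, at small problem sizes.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence


def brute_force_keyword_scores(sentences: Sequence[Sequence[str]]) -> dict[str, float]:
    """Keyword scores from first principles: enumerate every term pair,
    count sentence memberships with sets, normalize by the max raw score."""
    vocab = sorted({t for sent in sentences for t in sent})
    member = {t: {i for i, sent in enumerate(sentences) if t in sent} for t in vocab}
    raw = {}
    for a in vocab:
        total = 0.0
        for b in vocab:
            if a == b:
                continue
            both = len(member[a] & member[b])
            if both:
                total += both * both / (len(member[a]) * len(member[b]))
        raw[a] = total
    top = max(raw.values(), default=0.0)
    if top == 0.0:
        return raw
    return {t: r / top for t, r in raw.items()}


def brute_force_retrieval_score(
    query: Mapping[str, float],
    term_counts: Mapping[str, int],
    all_profiles: Sequence[Mapping[str, int]],
    idf_floor: float = 1e-6,
) -> float:
    """Retrieval score from the stated formula, recomputed without any
    index structure: df by scanning every profile, per-term accumulation."""
    n_docs = len(all_profiles)
    doc_len = sum(term_counts.values())
    overlap = [t for t in query if term_counts.get(t, 0) > 0]
    if not overlap or not query:
        return 0.0
    acc = 0.0
    for t in overlap:
        df = sum(1 for p in all_profiles if t in p and p[t] > 0)
        idf = max(1.0 + math.log(n_docs / (df + 1)), idf_floor)
        acc += query[t] * idf * idf * math.sqrt(term_counts[t]) / math.sqrt(doc_len)
    return (len(overlap) / len(query)) * acc


def brute_force_pair_metrics(
    clusters: Mapping[str, str], truth: Mapping[str, str]
) -> tuple[float, float]:
    """Pairwise precision/recall by explicit pair enumeration over items
    (items keyed by any hashable id; same key space in both mappings)."""
    items = sorted(truth)
    tp = cc = ci = 0
    for i, a in enumerate(items):
        for b in items[i + 1:]:
            same_c = clusters[a] == clusters[b]
            same_i = truth[a] == truth[b]
            cc += same_c
            ci += same_i
            tp += same_c and same_i
    precision = 1.0 if cc == 0 else tp / cc
    recall = 1.0 if ci == 0 else tp / ci
    return precision, recall
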