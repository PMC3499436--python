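"""Benchmark logic and clustering-recovery metrics.

Two kinds of evaluation:

* the cited-author benchmark — given a ranked expert list for a manuscript
  abstract, skip any suggestion who is an author of the manuscript itself
  and check whether the first remaining suggestion authored one of the
  manuscript's cited references;
* pairwise cluster precision/recall of a disambiguation against ground
  truth, computed over pairs of same-name authorships: precision is the
  fraction of co-clustered pairs that belong to the same true identity,
  recall the fraction of same-identity pairs that were co-clustered.
  Atomization (over-splitting one scientist) lowers recall but not
  precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import IO, Iterable, Mapping, Sequence

from .disambiguation import DisambiguatedAuthor
from .expert_index import RankedExpert

__all__ = [
    "BenchmarkCase",
    "ClusterMetrics",
    "cited_author_check",
    "pairwise_cluster_metrics",
]


@dataclass(frozen=True)
class BenchmarkCase:
    """One manuscript with its cited and self author name keys (may overlap)."""

    query_text: str
    cited_author_keys: frozenset[str]
    self_author_keys: frozenset[str]

    @classmethod
    def from_json(cls, line: str) -> "BenchmarkCase":
        obj = json.loads(line)
        return cls(
            query_text=obj["query_text"],
            cited_author_keys=frozenset(obj["cited_author_keys"]),
            self_author_keys=frozenset(obj.get("self_author_keys", [])),
        )


def _result_name_key(hit: RankedExpert) -> str:
    return hit.author_id.rsplit("#", 1)[0]


def cited_author_check(
    results: Sequence[RankedExpert], case: BenchmarkCase
) -> tuple[bool, int | None]:
    """Evaluate the top non-self suggestion against the cited authors.

    Scans results in rank order, skipping experts whose name key is a
    manuscript author; the first non-self expert is the top suggestion.
    Returns (hit, rank) where hit says whether that expert's name key is
    among the cited authors and rank is its 1-based position among
    non-self results. When every result is a self author (or results are
    empty) returns (False, None).
    """
    rank = 0
    for hit in results:
        key = _result_name_key(hit)
        if key in case.self_author_keys:
            continue
        rank += 1
        return key in case.cited_author_keys, rank
    return False, None


@dataclass(frozen=True)
class ClusterMetrics:
    """Pairwise precision/recall/F1; a vacuous flag marks an undefined
    denominator reported as 1.0 (e.g. all-singleton predictions)."""

    precision: float
    recall: float
    f1: float
    precision_vacuous: bool = False
    recall_vacuous: bool = False


def pairwise_cluster_metrics(
    predicted: Mapping[str, Iterable[DisambiguatedAuthor]],
    truth: Mapping[tuple[str, str], str],
) -> ClusterMetrics:
    """Pairwise clustering accuracy of ``predicted`` against ``truth``.

    ``predicted`` maps each name key to its profiles; ``truth`` maps
    (pmid, name_key) authorships to identity ids. Both must cover exactly
    the same authorships for the name keys under evaluation.
    """
    predicted_cluster: dict[tuple[str, str], str] = {}
    for name_key, profiles in predicted.items():
        for profile in profiles:
            for pmid in profile.pmids:
                predicted_cluster[(pmid, name_key)] = profile.author_id

    truth_authorships = set(truth)
    eval_keys = {key for (_pmid, key) in truth_authorships}
    covered = {a for a in predicted_cluster if a[1] in eval_keys}
    if covered != truth_authorships:
        missing = truth_authorships - covered
        extra = covered - truth_authorships
        raise ValueError(
            f"coverage mismatch: {len(missing)} truth authorships unpredicted, "
            f"{len(extra)} predicted authorships unlabeled"
        )

    tp = co_clustered = co_identical = 0
    by_key: dict[str, list[tuple[str, str]]] = {}
    for authorship in truth_authorships:
        by_key.setdefault(authorship[1], []).append(authorship)
    for authorships in by_key.values():
        for a, b in combinations(sorted(authorships), 2):
            same_cluster = predicted_cluster[a] == predicted_cluster[b]
            same_identity = truth[a] == truth[b]
            co_clustered += same_cluster
            co_identical += same_identity
            tp += same_cluster and same_identity

    precision_vacuous = co_clustered == 0
    recall_vacuous = co_identical == 0
    precision = 1.0 if precision_vacuous else tp / co_clustered
    recall = 1.0 if recall_vacuous else tp / co_identical
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return ClusterMetrics(
        precision=precision,
        recall=recall,
        f1=f1,
        precision_vacuous=precision_vacuous,
        recall_vacuous=recall_vacuous,
    )
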