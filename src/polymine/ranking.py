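"""Aggregation of evidence into ranked, Z-scored association candidates.

The raw relevancy score (R-score) of a candidate target is the sum of its
non-negated evidence-sentence scores — the more frequently, tightly and
strongly a pair co-occurs, the higher it scores. R-scores are standardized
to Z-scores across all co-occurring candidates of the query (population
standard deviation); candidates at or below the candidate-set average
(z ≤ 0) are borderline associations and removed by default to boost
precision, at the cost of a little recall. An option keeps them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .scoring import EvidenceSentence, ScoringConfig

__all__ = [
    "AssociationResult",
    "QueryResult",
    "aggregate",
    "compute_zscores",
    "filter_borderline",
    "assemble",
    "result_to_json",
]


@dataclass
class AssociationResult:
    """One candidate target with its R-score, Z-score and evidence."""

    target_entry_id: str
    target_category: str
    canonical_name: str
    synonyms: tuple[str, ...]
    raw_score: float
    z_score: float
    evidence: list[EvidenceSentence] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class QueryResult:
    """A completed query: settings echo plus the ranked candidate list."""

    query_term: str
    query_category: str
    target_category: str
    settings: dict
    results: list[AssociationResult] = field(default_factory=list)
    #: (doc_id, sentence_index) → sentence text, for evidence display
    sentence_texts: dict[tuple[str, int], str] = field(default_factory=dict)


def aggregate(evidence: Sequence[EvidenceSentence]) -> dict[str, float]:
    """Per-target sum of non-negated evidence scores; zero totals omitted."""
    totals: dict[str, float] = {}
    for ev in evidence:
        if ev.negated:
            continue
        totals[ev.target_entry_id] = totals.get(ev.target_entry_id, 0.0) + ev.score
    return {t: s for t, s in totals.items() if s > 0.0}


def compute_zscores(raw_scores: Mapping[str, float]) -> dict[str, float]:
    """Standardize R-scores over the candidate set.

    Uses the population standard deviation; a zero-variance set (including
    a single candidate) yields all-zero Z-scores — every candidate is then
    exactly average, i.e. borderline.
    """
    if not raw_scores:
        return {}
    targets = list(raw_scores)
    values = np.array([raw_scores[t] for t in targets], dtype=float)
    sd = float(values.std())  # population sd (ddof=0)
    if sd == 0.0:
        return {t: 0.0 for t in targets}
    z = (values - values.mean()) / sd
    return {t: float(zi) for t, zi in zip(targets, z)}


def filter_borderline(
    results: Sequence[AssociationResult], include_borderline: bool
) -> list[AssociationResult]:
    """Drop z ≤ 0 candidates unless borderline cases are requested."""
    if include_borderline:
        return list(results)
    return [r for r in results if r.z_score > 0.0]


def _sorted_evidence(evidence: Sequence[EvidenceSentence]) -> list[EvidenceSentence]:
    return sorted(evidence, key=lambda e: (-e.score, e.doc_id, e.sentence_index))


def assemble(
    query_term: str,
    query_category: str,
    target_category: str,
    results: Sequence[AssociationResult],
    config: ScoringConfig,
) -> QueryResult:
    """Build the final result: sorted candidates, settings echoed."""
    ordered = sorted(
        results,
        key=lambda r: (-r.z_score, -r.raw_score, r.target_entry_id),
    )
    for r in ordered:
        r.evidence = _sorted_evidence(r.evidence)
    return QueryResult(
        query_term=query_term,
        query_category=query_category,
        target_category=target_category,
        settings=config.to_dict(),
        results=list(ordered),
    )


def _round4(x: float) -> float:
    return round(x + 0.0, 4)


def result_to_json(
    result: QueryResult, sentence_texts: Mapping[tuple[str, int], str] | None = None
) -> str:
    """Serialize a :class:`QueryResult` to the fixed JSON layout.

    Scores carry 4 decimal places; *sentence_texts* maps
    ``(doc_id, sentence_index)`` to the evidence sentence text for display.
    """
    if sentence_texts is None:
        sentence_texts = result.sentence_texts
    payload = {
        "query": {
            "term": result.query_term,
            "category": result.query_category,
            "target_category": result.target_category,
        },
        "settings": result.settings,
        "results": [
            {
                "target_id": r.target_entry_id,
                "category": r.target_category,
                "name": r.canonical_name,
                "synonyms": list(r.synonyms),
                "raw_score": _round4(r.raw_score),
                "z_score": _round4(r.z_score),
                "counts": dict(sorted(r.counts.items())),
                "evidence": [
                    {
                        "doc_id": e.doc_id,
                        "sentence_index": e.sentence_index,
                        "category": e.category,
                        "span": e.span,
                        "score": _round4(e.score),
                        "negated": e.negated,
                        "query_span": list(e.query_char_span)
                        if e.query_char_span
                        else None,
                        "target_span": list(e.target_char_span),
                        "text": sentence_texts.get((e.doc_id, e.sentence_index), ""),
                    }
                    for e in r.evidence
                ],
            }
            for r in result.results
        ],
    }
    return json.dumps(payload, ensure_ascii=False, indent=2)
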