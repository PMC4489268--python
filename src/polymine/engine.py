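"""End-to-end query orchestration.

A query is "given X, find all associated Ys": the query term is expanded
through the thesaurus to its synonym list (or used verbatim in keyword
mode), the top-N relevant documents are retrieved, mentions are tagged,
candidate sentences classified and scored, per-target R-scores aggregated,
Z-scores computed over the co-occurring candidate set, borderline
associations filtered, and the ranked result assembled.

ALL-target queries run one Z-score universe per target category — score
scales differ between categories, so pooling them would conflate the
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus import CorpusIndex, Document, retrieve
from .errors import CorpusError, QueryError
from .ranking import (
    AssociationResult,
    QueryResult,
    aggregate,
    assemble,
    compute_zscores,
    filter_borderline,
)
from .scoring import EvidenceSentence, ScoringConfig, classify_document
from .textutils import normalize_term
from .thesaurus import TermMatcher, Thesaurus, tag_mentions

__all__ = ["QuerySpec", "QUERY_PSEUDO_ID", "expand_query", "run_query"]

#: Internal entry id under which the expanded query synonyms are tagged;
#: never collides with thesaurus entry ids.
QUERY_PSEUDO_ID = "__query__"
ALL_CATEGORIES = "ALL"


@dataclass
class QuerySpec:
    """One association query plus its options."""

    query_term: str
    query_category: str
    target_category: str = ALL_CATEGORIES
    custom_synonyms: list[str] | None = None
    custom_targets: list[str] | None = None
    config: ScoringConfig = field(default_factory=ScoringConfig)

    def __post_init__(self) -> None:
        if not self.query_term.strip():
            raise QueryError("query_term must be non-empty")


def expand_query(spec: QuerySpec, thesaurus: Thesaurus) -> tuple[list[str], str | None]:
    """Resolve the query term to its synonym list.

    Returns ``(synonyms, entry_id)``; ``entry_id`` is ``None`` in keyword
    mode (term not in the thesaurus). ``custom_synonyms``, when given,
    replace the automatic expansion. A term matching several entries of the
    query category is ambiguous and raises :class:`QueryError` listing the
    candidates.
    """
    matches = thesaurus.lookup(spec.query_term, spec.query_category)
    if len(matches) > 1:
        ids = ", ".join(sorted(e.entry_id for e in matches))
        raise QueryError(
            f"query term {spec.query_term!r} is ambiguous in category "
            f"{spec.query_category!r}: candidates {ids}"
        )
    entry_id = matches[0].entry_id if matches else None
    if spec.custom_synonyms is not None:
        syns = [normalize_term(s) for s in spec.custom_synonyms]
        return [s for s in syns if s], entry_id
    if matches:
        return list(matches[0].synonyms), entry_id
    return [normalize_term(spec.query_term)], entry_id


def _combined_matcher(
    thesaurus: Thesaurus, categories: list[str], query_synonyms: list[str]
) -> TermMatcher:
    matcher = TermMatcher()
    for cat in categories:
        for entry in thesaurus.categories.get(cat, ()):
            for syn in entry.synonyms:
                matcher.add(syn, entry.entry_id, entry.category)
    for syn in query_synonyms:
        matcher.add(syn, QUERY_PSEUDO_ID, QUERY_PSEUDO_ID)
    return matcher


def run_query(
    spec: QuerySpec,
    thesaurus: Thesaurus,
    index: CorpusIndex,
    documents: list[Document],
) -> QueryResult:
    """Execute the full pipeline and return the ranked result."""
    if not documents:
        raise CorpusError("corpus is empty")
    if spec.target_category != ALL_CATEGORIES and (
        spec.target_category not in thesaurus.categories
    ):
        raise QueryError(
            f"target category {spec.target_category!r} not in thesaurus"
        )
    if spec.custom_targets:
        missing = [t for t in spec.custom_targets if t not in thesaurus]
        if missing:
            raise QueryError(f"custom targets not in thesaurus: {missing}")

    synonyms, query_entry_id = expand_query(spec, thesaurus)
    categories = (
        sorted(thesaurus.categories)
        if spec.target_category == ALL_CATEGORIES
        else [spec.target_category]
    )

    doc_ids = retrieve(index, synonyms, spec.config.doc_limit)
    by_id = {d.doc_id: d for d in documents}
    retrieved = [by_id[d] for d in doc_ids if d in by_id]

    matcher = _combined_matcher(thesaurus, categories, synonyms)
    doc_mentions = [
        (doc, tag_mentions(doc.sentences, matcher, doc.text)) for doc in retrieved
    ]

    custom = set(spec.custom_targets) if spec.custom_targets else None
    sentence_texts: dict[tuple[str, int], str] = {}
    results: list[AssociationResult] = []
    for cat in categories:
        evidence: list[EvidenceSentence] = []
        for doc, mentions in doc_mentions:
            evidence.extend(
                classify_document(doc, mentions, QUERY_PSEUDO_ID, cat, spec.config)
            )
        # never report the query entity as its own association
        evidence = [e for e in evidence if e.target_entry_id != query_entry_id]
        if custom is not None:
            evidence = [e for e in evidence if e.target_entry_id in custom]
        raw = aggregate(evidence)
        zs = compute_zscores(raw)
        by_target: dict[str, list[EvidenceSentence]] = {}
        for ev in evidence:
            by_target.setdefault(ev.target_entry_id, []).append(ev)
        cat_results = []
        for target_id, score in raw.items():
            entry = thesaurus.entry(target_id)
            evs = by_target[target_id]
            counts: dict[str, int] = {}
            for ev in evs:
                if not ev.negated:
                    counts[ev.source] = counts.get(ev.source, 0) + 1
            for ev in evs:
                doc = by_id[ev.doc_id]
                sent = doc.sentences[ev.sentence_index]
                sentence_texts[(ev.doc_id, ev.sentence_index)] = doc.text[
                    sent.char_start : sent.char_end
                ]
            cat_results.append(
                AssociationResult(
                    target_entry_id=target_id,
                    target_category=entry.category,
                    canonical_name=entry.canonical_name,
                    synonyms=entry.synonyms,
                    raw_score=score,
                    z_score=zs[target_id],
                    evidence=evs,
                    counts=counts,
                )
            )
        results.extend(
            filter_borderline(cat_results, spec.config.include_borderline)
        )

    result = assemble(
        spec.query_term,
        spec.query_category,
        spec.target_category,
        results,
        spec.config,
    )
    result.sentence_texts = sentence_texts
    return result
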