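"""Sentence-level relevancy scoring of query/target co-occurrences.

Each candidate sentence is assigned one of four relevancy tiers:

* **R1** — query and target co-occur in the sentence together with at least
  one *filter word* (a word signifying a strong association, e.g.
  "catalyzes" in "Enzyme X catalyzes reaction Y").
* **R2** — query and target co-occur in the sentence without a filter word.
* **R3** — the sentence contains the target and a filter word, and the
  query occurs elsewhere in the same document.
* **R4** — the sentence contains the target only, the query occurring
  elsewhere in the same document.

R1/R2 scores are damped by a *tightness* factor ``1 / (1 + alpha * span)``
where ``span`` counts the tokens strictly between the nearest query and
target mentions — tight co-occurrence patterns are stronger evidence than
distant ones. Evidence found in curated database records is multiplied by a
weight boost (default 2.0) reflecting their higher credibility relative to
free-text articles. Sentences containing a negation word contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .corpus import Document, load_word_list
from .thesaurus import Mention

__all__ = [
    "ScoringConfig",
    "EvidenceSentence",
    "classify_sentence",
    "classify_document",
    "tightness_factor",
    "detect_negation",
    "contains_filter_word",
    "sentence_score",
    "score_document",
]

CATEGORIES = ("R1", "R2", "R3", "R4")

DEFAULT_BASE_WEIGHTS = {"R1": 50.0, "R2": 25.0, "R3": 5.0, "R4": 1.0}


@dataclass(frozen=True)
class ScoringConfig:
    """All scoring tunables.

    base_weights
        Per-tier base scores; must be non-increasing R1 → R4.
    tightness_alpha
        Per-token decay rate of the tightness factor (≥ 0).
    db_boost
        Multiplier (≥ 1) applied to evidence from database records.
    filter_words / negation_words
        Normalized words or phrases; ``None`` selects the packaged default
        lists.
    doc_limit
        Retrieval cap — how many top-ranked documents are mined.
    include_borderline
        Keep associations with zero or negative Z-scores (higher recall at
        the cost of precision).
    """

    base_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_WEIGHTS)
    )
    tightness_alpha: float = 0.02
    db_boost: float = 2.0
    filter_words: frozenset[str] | None = None
    negation_words: frozenset[str] | None = None
    doc_limit: int = 2000
    include_borderline: bool = False

    def __post_init__(self) -> None:
        w = self.base_weights
        if not (w["R1"] >= w["R2"] >= w["R3"] >= w["R4"] >= 0):
            raise ValueError("base weights must satisfy R1 >= R2 >= R3 >= R4 >= 0")
        if self.db_boost < 1:
            raise ValueError(f"db_boost must be >= 1, got {self.db_boost}")
        if self.tightness_alpha < 0:
            raise ValueError("tightness_alpha must be >= 0")
        if self.doc_limit < 1:
            raise ValueError("doc_limit must be >= 1")
        if self.filter_words is None:
            object.__setattr__(
                self,
                "filter_words",
                frozenset(load_word_list(None, "filter_words.txt")),
            )
        if self.negation_words is None:
            object.__setattr__(
                self,
                "negation_words",
                frozenset(load_word_list(None, "negation_words.txt")),
            )

    def with_options(self, **kwargs) -> "ScoringConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        """JSON-serializable settings echo."""
        return {
            "base_weights": {k: self.base_weights[k] for k in CATEGORIES},
            "tightness_alpha": self.tightness_alpha,
            "db_boost": self.db_boost,
            "doc_limit": self.doc_limit,
            "include_borderline": self.include_borderline,
            "n_filter_words": len(self.filter_words or ()),
            "n_negation_words": len(self.negation_words or ()),
        }


@dataclass(frozen=True)
class EvidenceSentence:
    """One scored co-occurrence sentence for one candidate target.

    ``span`` is defined only for the co-occurrence tiers R1/R2 (``None``
    for R3/R4); ``query_char_span`` is ``None`` when the query mention lies
    in a different sentence. Negated evidence carries score 0 and is
    excluded from aggregation.
    """

    doc_id: str
    sentence_index: int
    target_entry_id: str
    category: str
    span: int | None
    negated: bool
    score: float
    query_char_span: tuple[int, int] | None
    target_char_span: tuple[int, int]
    source: str = ""


def tightness_factor(span: int, alpha: float) -> float:
    """Hyperbolic decay ``1 / (1 + alpha * span)``; 1 at span 0."""
    if span < 0:
        raise ValueError(f"span must be >= 0, got {span}")
    return 1.0 / (1.0 + alpha * span)


def _phrase_hits(folded_tokens: Sequence[str], phrases: frozenset[str]) -> bool:
    """True when any word or contiguous token run in *phrases* occurs."""
    if not phrases:
        return False
    max_len = max(len(p.split()) for p in phrases)
    n = len(folded_tokens)
    for i in range(n):
        for k in range(1, min(max_len, n - i) + 1):
            if " ".join(folded_tokens[i : i + k]) in phrases:
                return True
    return False


def detect_negation(
    tokens: Sequence[str], negation_words: frozenset[str]
) -> bool:
    """True iff any token or contiguous token bigram is a negation word."""
    folded = [t.casefold() for t in tokens]
    for i, tok in enumerate(folded):
        if tok in negation_words:
            return True
        if i + 1 < len(folded) and f"{tok} {folded[i + 1]}" in negation_words:
            return True
    return False


def contains_filter_word(
    tokens: Sequence[str], filter_words: frozenset[str]
) -> bool:
    """True iff the sentence contains a filter word or phrase."""
    return _phrase_hits([t.casefold() for t in tokens], filter_words)


def _pair_span(q: Mention, t: Mention) -> int:
    """Tokens strictly between two mentions in one sentence (0 if adjacent
    or overlapping)."""
    if q.token_end <= t.token_start:
        return t.token_start - q.token_end
    if t.token_end <= q.token_start:
        return q.token_start - t.token_end
    return 0


def classify_sentence(
    sentence_mentions: Sequence[Mention],
    query_entry_id: str,
    target_category: str,
    filter_words: frozenset[str],
    sentence_tokens: Sequence[str],
    query_in_document: bool,
) -> list[dict]:
    """Tier assignments for the targets mentioned in one sentence.

    Returns one record per target entry present:
    ``{"target_entry_id", "category", "span", "query_char_span",
    "target_char_span"}``. ``category`` is ``None`` when no tier applies
    (no query co-occurrence and the query absent from the document).
    """
    has_filter = contains_filter_word(sentence_tokens, filter_words)
    query_mentions = [m for m in sentence_mentions if m.entry_id == query_entry_id]
    targets: dict[str, list[Mention]] = {}
    for m in sentence_mentions:
        if m.category == target_category and m.entry_id != query_entry_id:
            targets.setdefault(m.entry_id, []).append(m)

    out = []
    for target_id, tms in sorted(targets.items()):
        if query_mentions:
            best: tuple[int, Mention, Mention] | None = None
            for qm in query_mentions:
                # Skip degenerate self-overlap (shared span from an
                # ambiguous surface form): the same textual occurrence
                # cannot co-occur with itself.
                for tm in tms:
                    if (qm.token_start, qm.token_end) == (
                        tm.token_start,
                        tm.token_end,
                    ):
                        continue
                    s = _pair_span(qm, tm)
                    if best is None or s < best[0]:
                        best = (s, qm, tm)
            if best is not None:
                span, qm, tm = best
                out.append(
                    {
                        "target_entry_id": target_id,
                        "category": "R1" if has_filter else "R2",
                        "span": span,
                        "query_char_span": (qm.char_start, qm.char_end),
                        "target_char_span": (tm.char_start, tm.char_end),
                    }
                )
                continue
        if query_in_document and not query_mentions:
            tm = tms[0]
            out.append(
                {
                    "target_entry_id": target_id,
                    "category": "R3" if has_filter else "R4",
                    "span": None,
                    "query_char_span": None,
                    "target_char_span": (tm.char_start, tm.char_end),
                }
            )
    return out


def sentence_score(
    category: str, span: int | None, record_kind: str, config: ScoringConfig
) -> float:
    """Evidence score: tier base weight × tightness (R1/R2) × db boost."""
    score = float(config.base_weights[category])
    if category in ("R1", "R2"):
        score *= tightness_factor(span or 0, config.tightness_alpha)
    if record_kind == "database_record":
        score *= config.db_boost
    return score


def classify_document(
    doc: Document,
    mentions: Sequence[Mention],
    query_entry_id: str,
    target_category: str,
    config: ScoringConfig,
) -> list[EvidenceSentence]:
    """Classify and score every candidate sentence of one document."""
    by_sentence: dict[int, list[Mention]] = {}
    for m in mentions:
        by_sentence.setdefault(m.sentence_index, []).append(m)
    query_in_doc = any(m.entry_id == query_entry_id for m in mentions)

    evidence: list[EvidenceSentence] = []
    for sent in doc.sentences:
        sent_mentions = by_sentence.get(sent.index, [])
        if not sent_mentions:
            continue
        tokens = [t for t, _, _ in sent.tokens]
        negated = detect_negation(tokens, config.negation_words)
        for rec in classify_sentence(
            sent_mentions,
            query_entry_id,
            target_category,
            config.filter_words,
            tokens,
            query_in_doc,
        ):
            if rec["category"] is None:
                continue
            score = (
                0.0
                if negated
                else sentence_score(
                    rec["category"], rec["span"], doc.record_kind, config
                )
            )
            evidence.append(
                EvidenceSentence(
                    doc_id=doc.doc_id,
                    sentence_index=sent.index,
                    target_entry_id=rec["target_entry_id"],
                    category=rec["category"],
                    span=rec["span"],
                    negated=negated,
                    score=score,
                    query_char_span=rec["query_char_span"],
                    target_char_span=rec["target_char_span"],
                    source=doc.source,
                )
            )
    return evidence


# backwards-friendly alias used by the engine
score_document = classify_document
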