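"""Evaluation of predicted associations against a labelled gold standard.

The gold standard is closed-world over an explicit positive set and an
explicit negative set of entry ids; predictions outside that universe are
not judged (they are counted separately). Precision, recall, F-measure and
accuracy follow the usual contingency definitions.

Gold file format: TSV with columns ``query_term``, ``entry_id``,
``label`` ∈ {positive, negative}; ``#`` comments skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import DataError

__all__ = ["GoldStandard", "EvalReport", "evaluate", "load_gold_standard"]


@dataclass(frozen=True)
class GoldStandard:
    query_term: str
    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise DataError(
                f"gold standard labels overlap: {sorted(overlap)[:5]}"
            )

    @property
    def universe(self) -> frozenset[str]:
        return self.positives | self.negatives


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    fn: int
    tn: int
    unjudged: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / total if total else 0.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "unjudged": self.unjudged,
            "precision": round(self.precision, 4),
            "recall": round(self.recall, 4),
            "f_measure": round(self.f_measure, 4),
            "accuracy": round(self.accuracy, 4),
        }


def evaluate(predicted: set[str], gold: GoldStandard) -> EvalReport:
    """Score *predicted* entry ids against *gold*.

    Predictions outside the gold universe are excluded from the counts and
    reported as ``unjudged``. Raises :class:`DataError` on an empty gold
    universe.
    """
    if not gold.universe:
        raise DataError("gold standard universe is empty")
    judged = predicted & gold.universe
    return EvalReport(
        tp=len(judged & gold.positives),
        fp=len(judged & gold.negatives),
        fn=len(gold.positives - judged),
        tn=len(gold.negatives - judged),
        unjudged=len(predicted - gold.universe),
    )


def load_gold_standard(path: str | Path, query_term: str | None = None) -> GoldStandard:
    """Read a gold-standard TSV; *query_term* filters multi-query files."""
    positives: set[str] = set()
    negatives: set[str] = set()
    term: str | None = query_term
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise DataError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(cols)}"
                )
            qterm, entry_id, label = (c.strip() for c in cols[:3])
            if query_term is not None and qterm != query_term:
                continue
            term = term or qterm
            if label == "positive":
                positives.add(entry_id)
            elif label == "negative":
                negatives.add(entry_id)
            else:
                raise DataError(
                    f"{path}: line {lineno}: label must be positive|negative, "
                    f"got {label!r}"
                )
    if term is None:
        raise DataError(f"{path}: no gold rows found")
    return GoldStandard(term, frozenset(positives), frozenset(negatives))
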