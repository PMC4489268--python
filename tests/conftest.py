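"""Shared fixtures: tiny hand-built thesauri and corpora."""

from __future__ import annotations

import json
import random

import pytest

from polymine.corpus import Document
from polymine.thesaurus import Thesaurus, ThesaurusEntry


def make_entry(entry_id, category, canonical, synonyms=None):
    from polymine.textutils import normalize_term

    syns = synonyms or [canonical]
    norm = []
    for s in syns:
        n = normalize_term(s)
        if n not in norm:
            norm.append(n)
    if normalize_term(canonical) not in norm:
        norm.append(normalize_term(canonical))
    return ThesaurusEntry(entry_id, category, canonical, tuple(norm))


@pytest.fixture
def bpa_thesaurus() -> Thesaurus:
    """Toxin + disease thesaurus around the bisphenol A example."""
    return Thesaurus(
        {
            "toxin": [
                make_entry("X0001", "toxin", "bisphenol A", ["bisphenol A", "BPA"]),
            ],
            "disease": [
                make_entry(
                    "D0001",
                    "disease",
                    "breast neoplasms",
                    ["breast neoplasms", "breast cancer"],
                ),
            ],
        }
    )


@pytest.fixture
def write_thesaurus(tmp_path):
    def _write(rows, name="thesaurus.tsv"):
        path = tmp_path / name
        lines = ["\t".join(r) for r in rows]
        path.write_text("\n".join(lines) + "\n", "utf-8")
        return path

    return _write


@pytest.fixture
def write_corpus(tmp_path):
    def _write(records, name="corpus.jsonl"):
        path = tmp_path / name
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(rec) + "\n")
        return path

    return _write


def random_corpus(rng: random.Random, n_docs: int, vocab: list[str]) -> list[Document]:
    """Random short documents over *vocab* for oracle-equivalence checks."""
    docs = []
    for i in range(n_docs):
        n_sent = rng.randint(1, 5)
        sents = []
        for _ in range(n_sent):
            words = [rng.choice(vocab) for _ in range(rng.randint(1, 10))]
            words[0] = words[0].capitalize()
            sents.append(" ".join(words) + ".")
        docs.append(
            Document(
                doc_id=f"doc{i:03d}",
                source="rand",
                record_kind=rng.choice(["free_text", "database_record"]),
                title="" if rng.random() < 0.5 else "Random Title",
                body=" ".join(sents),
            )
        )
    return docs
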