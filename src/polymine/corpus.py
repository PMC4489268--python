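"""Document collections: reading, sentence splitting, indexing, retrieval.

A collection is a JSON-lines file, one document per line with fields
``doc_id``, ``source``, ``record_kind`` (``free_text`` or
``database_record``; curated database records later receive a scoring
weight boost), ``title`` and ``body``. The title, when present, is treated
as sentence 0 so that title co-occurrences are scoreable.

Retrieval ranks documents by raw synonym occurrence count — the simplest
deterministic reading of "top-N relevant documents" — and truncates to the
configured document cap (default 2000).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .errors import CorpusError
from .textutils import SHORT_TERM_LEN, tokenize

__all__ = [
    "Document",
    "Sentence",
    "CorpusIndex",
    "read_corpus",
    "split_sentences",
    "build_index",
    "retrieve",
    "load_word_list",
]

RECORD_KINDS = ("free_text", "database_record")

_SPLIT_CANDIDATE = re.compile(r"[.!?](?=\s+[A-Z0-9])")

INDEX_FORMAT_VERSION = 1


def load_word_list(source: str | Path | None, default: str | None = None) -> list[str]:
    """Read a one-term-per-line word list (UTF-8, ``#`` comments).

    With *source* ``None``, falls back to the packaged *default* list.
    Terms are returned stripped and case-folded, in file order.
    """
    if source is None:
        if default is None:
            return []
        text = (
            resources.files("polymine").joinpath(f"data/{default}").read_text("utf-8")
        )
    else:
        text = Path(source).read_text("utf-8")
    terms = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.append(line.casefold())
    return terms


def _abbreviations() -> tuple[str, ...]:
    return tuple(load_word_list(None, "abbreviations.txt"))


_ABBREVIATIONS: tuple[str, ...] | None = None


@dataclass(frozen=True)
class Sentence:
    """One sentence: position, character span and tokens.

    ``char_start``/``char_end`` are half-open offsets into the document
    text (title + newline + body); token offsets are absolute into the same
    stream and lie within the sentence span.
    """

    index: int
    char_start: int
    char_end: int
    tokens: tuple[tuple[str, int, int], ...]


@dataclass(frozen=True)
class Document:
    doc_id: str
    source: str = ""
    record_kind: str = "free_text"
    title: str = ""
    body: str = ""

    def __post_init__(self) -> None:
        if self.record_kind not in RECORD_KINDS:
            raise CorpusError(
                f"document {self.doc_id!r}: record_kind must be one of "
                f"{RECORD_KINDS}, got {self.record_kind!r}"
            )

    @property
    def text(self) -> str:
        """The character stream all offsets refer to."""
        return f"{self.title}\n{self.body}" if self.title else self.body

    @cached_property
    def sentences(self) -> tuple[Sentence, ...]:
        return tuple(split_sentences(self.title, self.body))


def read_corpus(path: str | Path) -> list[Document]:
    """Read a JSON-lines collection, preserving file order.

    Raises :class:`CorpusError` on a malformed line (with its line number),
    a missing or duplicate ``doc_id``.
    """
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}: line {lineno}: malformed JSON: {exc}")
            if not isinstance(rec, dict) or "doc_id" not in rec:
                raise CorpusError(f"{path}: line {lineno}: missing doc_id")
            doc_id = str(rec["doc_id"])
            if doc_id in seen:
                raise CorpusError(f"{path}: line {lineno}: duplicate doc_id {doc_id!r}")
            seen.add(doc_id)
            docs.append(
                Document(
                    doc_id=doc_id,
                    source=str(rec.get("source", "")),
                    record_kind=str(rec.get("record_kind", "free_text")),
                    title=str(rec.get("title", "")),
                    body=str(rec.get("body", "")),
                )
            )
    return docs


def _is_abbreviation(prefix: str) -> bool:
    """True when *prefix* ends in a known non-terminal abbreviation."""
    global _ABBREVIATIONS
    if _ABBREVIATIONS is None:
        _ABBREVIATIONS = _abbreviations()
    low = prefix.casefold()
    for abbr in _ABBREVIATIONS:
        if low.endswith(abbr):
            before = len(low) - len(abbr)
            if before == 0 or not low[before - 1].isalnum():
                return True
    return False


def split_sentences(title: str, body: str) -> list[Sentence]:
    """Rule-based sentence splitting with token offsets.

    The title (when non-empty) becomes sentence 0. The body splits after
    ``.``, ``!`` or ``?`` followed by whitespace and an uppercase letter or
    digit, unless the candidate ends a known abbreviation ("e.g.",
    "et al.", "Fig.", ...). Offsets refer to ``title + "\\n" + body`` when
    a title is present, else to ``body``.
    """
    sentences: list[Sentence] = []
    base = len(title) + 1 if title else 0

    def add(char_start: int, char_end: int, text: str) -> None:
        toks = tuple(
            (t, char_start + s, char_start + e) for t, s, e in tokenize(text)
        )
        sentences.append(
            Sentence(
                index=len(sentences),
                char_start=char_start,
                char_end=char_end,
                tokens=toks,
            )
        )

    if title:
        add(0, len(title), title)

    boundaries = [
        m.end()
        for m in _SPLIT_CANDIDATE.finditer(body)
        if not _is_abbreviation(body[: m.end()])
    ]
    start = 0
    for end in [*boundaries, len(body)]:
        segment = body[start:end]
        stripped = segment.strip()
        if stripped:
            lead = len(segment) - len(segment.lstrip())
            s = start + lead
            e = s + len(stripped)
            add(base + s, base + e, stripped)
        start = end
    return sentences


@dataclass
class CorpusIndex:
    """Inverted index over case-folded tokens plus per-document token streams.

    ``postings`` maps a token to ``(doc_id, term_frequency)`` pairs sorted
    by doc_id; the verbatim token streams support exact-case verification of
    short synonyms and multi-word phrase confirmation at retrieval time.
    """

    postings: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    doc_tokens: dict[str, list[str]] = field(default_factory=dict)

    @property
    def doc_count(self) -> int:
        return len(self.doc_tokens)

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": INDEX_FORMAT_VERSION,
            "postings": self.postings,
            "doc_tokens": self.doc_tokens,
        }
        Path(path).write_text(
            json.dumps(payload, ensure_ascii=False, sort_keys=True), "utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "CorpusIndex":
        payload = json.loads(Path(path).read_text("utf-8"))
        if payload.get("format_version") != INDEX_FORMAT_VERSION:
            raise CorpusError(
                f"{path}: unsupported index format_version "
                f"{payload.get('format_version')!r}"
            )
        return cls(
            postings={
                tok: [(d, int(tf)) for d, tf in plist]
                for tok, plist in payload["postings"].items()
            },
            doc_tokens={d: list(ts) for d, ts in payload["doc_tokens"].items()},
        )


def build_index(documents: Iterable[Document]) -> CorpusIndex:
    index = CorpusIndex()
    for doc in documents:
        toks = [t for t, _, _ in tokenize(doc.text)]
        index.doc_tokens[doc.doc_id] = toks
        counts: dict[str, int] = {}
        for tok in toks:
            folded = tok.casefold()
            counts[folded] = counts.get(folded, 0) + 1
        for tok, tf in counts.items():
            index.postings.setdefault(tok, []).append((doc.doc_id, tf))
    for plist in index.postings.values():
        plist.sort(key=lambda p: p[0])
    return index


def count_occurrences(tokens: Sequence[str], synonym: str) -> int:
    """Non-overlapping occurrences of *synonym* in a verbatim token stream.

    Short synonyms (≤ 4 characters) must match exact case; longer ones are
    compared case-folded.
    """
    pattern = tuple(t for t, _, _ in tokenize(synonym))
    if not pattern:
        return 0
    exact = len(synonym) <= SHORT_TERM_LEN
    if not exact:
        pattern = tuple(t.casefold() for t in pattern)
        tokens = [t.casefold() for t in tokens]
    count = 0
    i = 0
    k = len(pattern)
    while i <= len(tokens) - k:
        if tuple(tokens[i : i + k]) == pattern:
            count += 1
            i += k
        else:
            i += 1
    return count


def retrieve(index: CorpusIndex, synonyms: Sequence[str], limit: int = 2000) -> list[str]:
    """Doc ids containing ≥ 1 synonym, ranked by total occurrence count.

    Candidates are found through the first token of each synonym, then
    verified against the document token stream (full phrase, case rule).
    Ties break by doc_id ascending; the list is truncated to *limit*.
    """
    if limit < 1:
        raise ValueError(f"limit must be >= 1, got {limit}")
    scores: dict[str, int] = {}
    for syn in synonyms:
        toks = tokenize(syn)
        if not toks:
            continue
        first = toks[0][0].casefold()
        for doc_id, _tf in index.postings.get(first, ()):
            n = count_occurrences(index.doc_tokens[doc_id], syn)
            if n:
                scores[doc_id] = scores.get(doc_id, 0) + n
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [doc_id for doc_id, _ in ranked[:limit]]
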