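"""Category thesauri: loading, synonym normalization and mention tagging.

A thesaurus maps biomedical concepts (diseases, genes, drugs, toxins, ...)
to their synonym lists. Tagging scans tokenized sentences with a compiled
multi-pattern dictionary matcher and emits :class:`Mention` spans using
leftmost-longest, word-boundary matching. Matching is case-insensitive for
terms longer than four characters and exact-case for short symbols so that
"BPA" or "p53" never fires on unrelated lowercase text.

File format: 4-column TSV ``category<TAB>entry_id<TAB>canonical_name<TAB>
syn1|syn2|...``, UTF-8, ``#`` comment lines skipped.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ThesaurusError
from .textutils import SHORT_TERM_LEN, normalize_term, tokenize

__all__ = [
    "ThesaurusEntry",
    "Thesaurus",
    "Mention",
    "TermMatcher",
    "normalize_term",
    "load_thesaurus",
    "tag_mentions",
]


@dataclass(frozen=True)
class ThesaurusEntry:
    """One concept: id, category, canonical name and normalized synonyms."""

    entry_id: str
    category: str
    canonical_name: str
    synonyms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.synonyms:
            raise ThesaurusError(f"entry {self.entry_id!r} has no synonyms")
        if normalize_term(self.canonical_name) not in self.synonyms:
            raise ThesaurusError(
                f"entry {self.entry_id!r}: canonical name missing from synonyms"
            )


@dataclass(frozen=True)
class Mention:
    """A tagged occurrence of a thesaurus synonym in one sentence.

    Spans are 0-based half-open, at token level (within the sentence) and
    character level (into the document text).
    """

    entry_id: str
    category: str
    sentence_index: int
    token_start: int
    token_end: int
    char_start: int
    char_end: int
    matched_text: str


class TermMatcher:
    """Compiled multi-pattern matcher over token sequences.

    Patterns are keyed by their token tuple: short terms (≤ 4 characters)
    in a case-sensitive table, longer terms in a case-folded table. Lookup
    at a position tries the longest window first (leftmost-longest).
    """

    def __init__(self) -> None:
        self._exact: dict[tuple[str, ...], list[tuple[str, str]]] = {}
        self._folded: dict[tuple[str, ...], list[tuple[str, str]]] = {}
        self.max_tokens = 0

    def add(self, term: str, entry_id: str, category: str) -> None:
        """Register one normalized *term* for (*entry_id*, *category*)."""
        toks = tuple(t for t, _, _ in tokenize(term))
        if not toks:
            return
        table = self._exact if len(term) <= SHORT_TERM_LEN else self._folded
        key = toks if table is self._exact else tuple(t.casefold() for t in toks)
        table.setdefault(key, [])
        if (entry_id, category) not in table[key]:
            table[key].append((entry_id, category))
        self.max_tokens = max(self.max_tokens, len(toks))

    def match_at(
        self, tokens: Sequence[str], folded: Sequence[str], start: int
    ) -> tuple[int, list[tuple[str, str]]]:
        """Longest match starting at token *start*.

        Returns ``(match_len, [(entry_id, category), ...])``; match_len 0
        means no pattern fires here.
        """
        longest = min(self.max_tokens, len(tokens) - start)
        for length in range(longest, 0, -1):
            hits: list[tuple[str, str]] = []
            window = tuple(tokens[start : start + length])
            hits.extend(self._exact.get(window, ()))
            fwindow = tuple(folded[start : start + length])
            for hit in self._folded.get(fwindow, ()):
                if hit not in hits:
                    hits.append(hit)
            if hits:
                return length, hits
        return 0, []


@dataclass
class Thesaurus:
    """Entries grouped by category plus the compiled matcher."""

    categories: dict[str, list[ThesaurusEntry]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._matcher: TermMatcher | None = None
        self._by_id: dict[str, ThesaurusEntry] = {}
        for entries in self.categories.values():
            for entry in entries:
                if entry.entry_id in self._by_id:
                    raise ThesaurusError(f"duplicate entry_id {entry.entry_id!r}")
                self._by_id[entry.entry_id] = entry

    @property
    def matcher(self) -> TermMatcher:
        if self._matcher is None:
            m = TermMatcher()
            for entries in self.categories.values():
                for entry in entries:
                    for syn in entry.synonyms:
                        m.add(syn, entry.entry_id, entry.category)
            self._matcher = m
        return self._matcher

    def entry(self, entry_id: str) -> ThesaurusEntry:
        return self._by_id[entry_id]

    def __contains__(self, entry_id: str) -> bool:
        return entry_id in self._by_id

    def entries(self) -> Iterable[ThesaurusEntry]:
        for entries in self.categories.values():
            yield from entries

    def lookup(self, term: str, category: str | None = None) -> list[ThesaurusEntry]:
        """Entries whose synonym list contains normalized *term*."""
        norm = normalize_term(term)
        out = []
        for entry in self.entries():
            if category is not None and entry.category != category:
                continue
            if norm in entry.synonyms:
                out.append(entry)
        return out

    def restrict(self, categories: set[str]) -> "Thesaurus":
        """A view containing only the given categories."""
        return Thesaurus(
            {c: list(es) for c, es in self.categories.items() if c in categories}
        )


def load_thesaurus(
    path: str | Path, category_filter: set[str] | None = None
) -> Thesaurus:
    """Read a thesaurus TSV, keeping only *category_filter* categories.

    Raises :class:`ThesaurusError` on a short row (with its line number),
    a duplicate entry_id, or an entry with no usable synonym.
    """
    categories: dict[str, list[ThesaurusEntry]] = {}
    seen_ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ThesaurusError(
                    f"{path}: line {lineno}: expected 4 tab-separated columns, "
                    f"got {len(cols)}"
                )
            category, entry_id, canonical, syn_field = (c.strip() for c in cols[:4])
            if entry_id in seen_ids:
                raise ThesaurusError(
                    f"{path}: line {lineno}: duplicate entry_id {entry_id!r}"
                )
            seen_ids.add(entry_id)
            synonyms = []
            for raw in syn_field.split("|"):
                norm = normalize_term(raw)
                if norm and norm not in synonyms:
                    synonyms.append(norm)
            canon_norm = normalize_term(canonical)
            if canon_norm and canon_norm not in synonyms:
                synonyms.append(canon_norm)
            if not synonyms:
                raise ThesaurusError(
                    f"{path}: line {lineno}: entry {entry_id!r} has no synonym "
                    "left after normalization"
                )
            if category_filter is not None and category not in category_filter:
                continue
            categories.setdefault(category, []).append(
                ThesaurusEntry(entry_id, category, canonical, tuple(synonyms))
            )
    return Thesaurus(categories)


def tag_mentions(
    sentences: Sequence,
    thesaurus: Thesaurus | TermMatcher,
    text: str | None = None,
) -> list[Mention]:
    """Tag all dictionary mentions in tokenized *sentences*.

    *sentences* are :class:`polymine.corpus.Sentence`-shaped objects
    (``index`` and ``tokens`` of ``(text, char_start, char_end)``). Matching
    is leftmost-longest on word boundaries; an ambiguous surface form (one
    synonym shared by several entries) yields one mention per entry at the
    same span. Mentions come out sorted by ``(sentence_index, token_start)``.

    *text* is the document character stream the token offsets refer to; when
    given, ``matched_text`` is the exact substring, otherwise tokens joined
    by single spaces.
    """
    matcher = thesaurus.matcher if isinstance(thesaurus, Thesaurus) else thesaurus
    mentions: list[Mention] = []
    for sent in sentences:
        toks = [t for t, _, _ in sent.tokens]
        folded = [t.casefold() for t in toks]
        i = 0
        n = len(toks)
        while i < n:
            length, hits = matcher.match_at(toks, folded, i)
            if length == 0:
                i += 1
                continue
            char_start = sent.tokens[i][1]
            char_end = sent.tokens[i + length - 1][2]
            if text is not None:
                matched = text[char_start:char_end]
            else:
                matched = " ".join(toks[i : i + length])
            for entry_id, category in hits:
                mentions.append(
                    Mention(
                        entry_id=entry_id,
                        category=category,
                        sentence_index=sent.index,
                        token_start=i,
                        token_end=i + length,
                        char_start=char_start,
                        char_end=char_end,
                        matched_text=matched,
                    )
                )
            i += length
    mentions.sort(key=lambda m: (m.sentence_index, m.token_start, m.entry_id))
    return mentions
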