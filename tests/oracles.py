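"""Independent brute-force oracles for matcher and retrieval checks.

These scan every synonym against every token window directly, without the
compiled matcher or the inverted index, and are deliberately written
against the declared matching semantics (leftmost-longest, word
boundaries, 4-character case rule) rather than against the implementation.
"""

from __future__ import annotations

from polymine.corpus import Document
from polymine.textutils import SHORT_TERM_LEN, tokenize


def _syn_tokens(synonym: str) -> tuple[tuple[str, ...], bool]:
    """Token tuple of a synonym plus whether matching is exact-case."""
    toks = tuple(t for t, _, _ in tokenize(synonym))
    return toks, len(synonym) <= SHORT_TERM_LEN


def _window_matches(window: list[str], synonym: str) -> bool:
    pattern, exact = _syn_tokens(synonym)
    if len(pattern) != len(window):
        return False
    if exact:
        return tuple(window) == pattern
    return tuple(w.casefold() for w in window) == tuple(
        p.casefold() for p in pattern
    )


def brute_force_mentions(sentences, entries) -> list[tuple]:
    """All mentions as ``(sentence_index, token_start, token_end, entry_id)``.

    *entries* is an iterable of objects with ``entry_id`` and ``synonyms``.
    Selection is greedy leftmost-longest over each sentence.
    """
    table = [(e.entry_id, syn) for e in entries for syn in e.synonyms]
    out = []
    for sent in sentences:
        toks = [t for t, _, _ in sent.tokens]
        i = 0
        while i < len(toks):
            best_len = 0
            best_ids: list[str] = []
            for entry_id, syn in table:
                k = len(tuple(t for t, _, _ in tokenize(syn)))
                if k == 0 or i + k > len(toks):
                    continue
                if _window_matches(toks[i : i + k], syn):
                    if k > best_len:
                        best_len = k
                        best_ids = [entry_id]
                    elif k == best_len and entry_id not in best_ids:
                        best_ids.append(entry_id)
            if best_len == 0:
                i += 1
                continue
            for entry_id in sorted(best_ids):
                out.append((sent.index, i, i + best_len, entry_id))
            i += best_len
    return out


def brute_force_retrieve(
    documents: list[Document], synonyms: list[str], limit: int
) -> list[str]:
    """Full-scan retrieval: per-document total of non-overlapping synonym
    occurrence counts, ranked count-descending then doc_id-ascending."""
    scores: dict[str, int] = {}
    for doc in documents:
        toks = [t for t, _, _ in tokenize(doc.text)]
        total = 0
        for syn in synonyms:
            pattern, exact = _syn_tokens(syn)
            if not pattern:
                continue
            i = 0
            k = len(pattern)
            while i <= len(toks) - k:
                if _window_matches(toks[i : i + k], syn):
                    total += 1
                    i += k
                else:
                    i += 1
        if total:
            scores[doc.doc_id] = total
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [d for d, _ in ranked[:limit]]
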