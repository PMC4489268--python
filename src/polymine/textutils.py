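"""Shared term normalization and tokenization.

Every module that compares text — synonym matching, indexing, retrieval,
filter/negation word lookup — goes through these two functions so that a
term matches itself no matter where it was read from.
"""

from __future__ import annotations

import re

__all__ = ["normalize_term", "tokenize", "SHORT_TERM_LEN"]

#: Terms at or below this length keep their case ("BPA", "p53", "ATP");
#: longer terms are matched case-insensitively.
SHORT_TERM_LEN = 4

_WS_RUN = re.compile(r"\s+")

# A token is a maximal alphanumeric run; hyphens and parentheses are kept
# inside a token only when flanked by alphanumerics ("X-linked", "poly(A").
_TOKEN = re.compile(r"\w+(?:[-()]\w+)*")


def normalize_term(raw: str) -> str:
    """Canonicalize a term for dictionary matching.

    Strips surrounding whitespace, collapses internal whitespace runs to a
    single space, and case-folds terms longer than :data:`SHORT_TERM_LEN`
    characters. Short terms are preserved verbatim so that symbols such as
    "BPA" or "p53" stay case-sensitive.
    """
    term = _WS_RUN.sub(" ", raw.strip())
    if len(term) > SHORT_TERM_LEN:
        term = term.casefold()
    return term


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Split *text* into ``(token, char_start, char_end)`` triples.

    Boundaries are whitespace and punctuation; offsets are 0-based,
    half-open, into *text*.
    """
    return [(m.group(), m.start(), m.end()) for m in _TOKEN.finditer(text)]
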