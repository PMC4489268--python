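"""Exception hierarchy.

``DataError`` marks malformed user inputs (thesaurus/corpus/gold files,
inconsistent query specs); the CLI maps it to exit code 1 so scripts can
distinguish bad data from bad usage (exit 2).
"""


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class ThesaurusError(DataError):
    """Bad thesaurus file or entry."""


class CorpusError(DataError):
    """Bad corpus file or document record."""


class QueryError(DataError):
    """Inconsistent query specification."""
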