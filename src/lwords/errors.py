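"""Exception hierarchy for the lwords pipeline.

Every module raises a subclass of :class:`LwordsError`, so the CLI can turn
any pipeline failure into a one-line diagnostic and a nonzero exit status.
"""


class LwordsError(Exception):
    """Base class for all lwords errors."""


class FastaError(LwordsError):
    """Malformed FASTA input (empty record, bad character, duplicate id)."""


class WordLengthError(LwordsError):
    """Invalid word length (out of guard range, or longer than a sequence)."""


class QueryError(LwordsError):
    """Invalid suffix-tree query (bad alphabet, or deeper than a truncated tree)."""


class TreeError(LwordsError):
    """Invalid tree construction or serialization request."""
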