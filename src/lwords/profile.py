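"""Word-length selection and L-word frequency profiles.

The resolution of an alignment-free word-frequency comparison is set by a
single word length ``L``. Following the lower limit of the optimal
resolution range of Sims et al., ``L`` is the ceiling of the base-4
logarithm of the length ``m`` of the longest input sequence:

    m = max_i length(S_i),     L = ceil(log4 m),     t = 4**L.

The occurrence matrix ``O`` (n sequences x t words, overlapping occurrences
counted) and the row-normalized relative-frequency matrix ``F_L``
(``f_ij = O_ij / sum_j O_ij``) are the per-sequence composition profiles
that downstream distances are computed from.

Columns are always the full lexicographic word list ``W_L`` (A < C < G < T),
dense even when mostly zero, so matrices from different datasets with equal
``L`` are column-compatible.

Forward strand only: no reverse-complement folding is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .errors import LwordsError, WordLengthError
from .io import SequenceRecord, SequenceSet
from .suffixtree import GeneralizedSuffixTree

#: guard against runaway 4^L memory use (4^12 = 16.7M columns)
MAX_WORD_LENGTH = 12

_BASE4 = str.maketrans("ACGT", "0123")


@dataclass(frozen=True)
class WordLengthSelection:
    """Chosen word length and derived quantities.

    Attributes
    ----------
    m : int
        Length of the longest sequence, in bases.
    L : int
        Word length, in bases: ``ceil(log4 m)`` when auto-selected.
    t : int
        Number of possible L-words, ``4**L``.
    """

    m: int
    L: int

    @property
    def t(self) -> int:
        return 4 ** self.L


def select_word_length(seqs: SequenceSet) -> WordLengthSelection:
    """Auto-select the word length from the longest sequence.

    Computed in exact integer arithmetic (smallest ``L`` with ``4**L >= m``)
    rather than floating-point logarithms, so exact powers of 4 are never
    pushed up a level by rounding noise.
    """
    m = max(seqs.lengths)
    L = 1
    while 4 ** L < m:
        L += 1
    if L > MAX_WORD_LENGTH:
        raise WordLengthError(
            f"auto-selected L={L} exceeds the guard ({MAX_WORD_LENGTH})"
        )
    return WordLengthSelection(m=m, L=L)


def enumerate_words(L: int) -> list[str]:
    """The ordered word list ``W_L``: all 4^L words, lexicographic A<C<G<T."""
    if L < 1:
        raise WordLengthError("L must be >= 1")
    if L > MAX_WORD_LENGTH:
        raise WordLengthError(f"L={L} exceeds the guard ({MAX_WORD_LENGTH})")
    return ["".join(p) for p in product("ACGT", repeat=L)]


def word_index(w: str) -> int:
    """Lexicographic rank of an ACGT word among words of its length."""
    return int(w.translate(_BASE4), 4)


def occurrence_matrix(
    tree: GeneralizedSuffixTree, seqs: SequenceSet, sel: WordLengthSelection
) -> pd.DataFrame:
    """The n x t occurrence matrix ``O`` over the full word list ``W_L``.

    Counts come from a single bulk suffix-tree sweep
    (:meth:`~lwords.suffixtree.GeneralizedSuffixTree.count_all_words_at_depth`),
    densified over all 4^L columns; words absent from the data set get zero
    columns. Rows follow input order; for a pure-ACGT sequence the row sums
    to ``m_i - L + 1`` (one count per window).

    Raises
    ------
    WordLengthError
        If any sequence is shorter than ``L`` (it cannot form any L-word).
    """
    L = sel.L
    for rec in seqs:
        if len(rec) < L:
            raise WordLengthError(
                f"sequence {rec.id!r} (length {len(rec)}) cannot form any "
                f"L-word of length {L}"
            )
    if tree.ids != seqs.ids:
        raise LwordsError("tree was not built over this sequence set")

    counts = tree.count_all_words_at_depth(L)
    data = np.zeros((seqs.n, sel.t), dtype=np.int64)
    for word, vec in counts.items():
        data[:, word_index(word)] = vec
    return pd.DataFrame(data, index=seqs.ids, columns=enumerate_words(L))


def frequency_matrix(O: pd.DataFrame) -> pd.DataFrame:
    """Relative-frequency profiles ``F_L``: each row of ``O`` divided by its sum.

    Raises
    ------
    LwordsError
        If any row of ``O`` is all zero (the sequence contributed no valid
        L-word, e.g. it consists entirely of ambiguity symbols).
    """
    row_sums = O.sum(axis=1)
    zero = row_sums[row_sums == 0]
    if len(zero):
        raise LwordsError(
            f"sequence(s) with no valid L-words: {', '.join(map(repr, zero.index))}"
        )
    return O.div(row_sums, axis=0)


def oracle_counts(seq: SequenceRecord | str, L: int) -> np.ndarray:
    """Sliding-window word counts, independent of the suffix tree.

    Scans the ``m - L + 1`` windows of width ``L`` shifted one base at a
    time; windows containing a non-ACGT symbol are skipped. Returns the
    dense count vector over ``W_L`` in lexicographic order. This is the
    brute-force reference that the suffix-tree counts are tested against.
    """
    if L < 1:
        raise WordLengthError("L must be >= 1")
    residues = seq if isinstance(seq, str) else seq.residues
    out = np.zeros(4 ** L, dtype=np.int64)
    for p in range(len(residues) - L + 1):
        window = residues[p : p + L]
        try:
            out[int(window.translate(_BASE4), 4)] += 1
        except ValueError:  # window spans an ambiguity symbol
            continue
    return out
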