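"""Generalized suffix tree over a set of DNA sequences.

The tree is the workhorse of the pipeline: built once in (amortized) linear
time with Ukkonen's algorithm over the concatenation of all sequences, it
answers "how many times does word ``w`` occur in each sequence?" by a single
root-to-locus traversal, and enumerates the counts of *all* words of a fixed
length ``L`` in one depth-bounded sweep.

Construction
------------
Each sequence ``S_i`` is terminated by a sentinel symbol unique to that
sequence, drawn from the Unicode private-use area (disjoint from the IUPAC
alphabet by construction). The concatenation ``S_1 $_1 S_2 $_2 ...`` is fed
to a single Ukkonen pass. Because every sentinel occurs exactly once in the
text, no path to an internal node can contain one (two suffixes sharing a
prefix through ``$_i`` would imply two occurrences of ``$_i``); each leaf
edge is therefore trimmed, after construction, at the sentinel of the
sequence owning its suffix, which turns the plain suffix tree of the
concatenation into the generalized suffix tree of the set. Every suffix of
every sequence (including the bare sentinel) then ends at exactly one leaf,
so the total number of leaf annotations is ``sum(m_i + 1)``.

A depth-truncated variant (``max_depth=k``) stores only the first ``k``
symbols of every suffix, built directly as a compressed trie: word queries
for ``|w| <= k`` are identical to the full tree at a fraction of the memory.

Ambiguity codes (N, R, Y, ...) are kept in the tree as ordinary symbols so
the suffix structure is exact, but queries are restricted to the {A,C,G,T}
alphabet and any word window containing a non-ACGT symbol is never counted.
All traversals are iterative: genome-scale inputs must not hit Python's
recursion limit.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Iterator, Optional

import numpy as np

from .errors import LwordsError, QueryError
from .io import SequenceSet

_ACGT = frozenset("ACGT")
#: first code point of the per-sequence sentinel block (Unicode private use).
_SENTINEL_BASE = 0xE000
_MAX_SEQS = 0xF8FF - 0xE000  # private-use-area capacity


class _Node:
    """Tree node; edge label = text[start:end] of the edge *into* this node."""

    __slots__ = ("start", "end", "children", "slink", "annots")

    def __init__(self, start: int, end: Optional[int]):
        self.start = start
        self.end = end  # None = growing leaf (global end) during Ukkonen
        self.children: dict[str, "_Node"] = {}
        self.slink: Optional["_Node"] = None
        self.annots: list[tuple[int, int]] = []


class GeneralizedSuffixTree:
    """Compressed trie of all suffixes of all sequences in a set.

    Build with :func:`build_gst`; query with :meth:`count_word` and
    :meth:`count_all_words_at_depth`. Edge labels are (start, end) references
    into the shared concatenated text, never copied substrings.

    Attributes
    ----------
    n : int
        Number of sequences indexed.
    max_depth : int or None
        Truncation depth, or None for the full tree.
    """

    def __init__(self, seqs: SequenceSet, max_depth: Optional[int] = None):
        if seqs.n > _MAX_SEQS:
            raise LwordsError(f"at most {_MAX_SEQS} sequences supported")
        for rec in seqs:
            if len(rec) == 0:
                raise LwordsError(f"empty sequence {rec.id!r}")
        if max_depth is not None and max_depth < 1:
            raise LwordsError("max_depth must be >= 1")

        self.ids = list(seqs.ids)
        self.n = seqs.n
        self.lengths = list(seqs.lengths)
        self.max_depth = max_depth

        # concatenated text with one unique sentinel per sequence
        parts, starts = [], []
        pos = 0
        for i, rec in enumerate(seqs):
            starts.append(pos)
            parts.append(rec.residues)
            parts.append(chr(_SENTINEL_BASE + i))
            pos += len(rec) + 1
        self._text = "".join(parts)
        self._starts = starts  # global offset of each sequence

        if max_depth is None:
            self._root = self._build_ukkonen()
            self._finalize_full_tree()
        else:
            self._root = self._build_truncated(max_depth)

    # ------------------------------------------------------------------ build

    def _build_ukkonen(self) -> _Node:
        """Single Ukkonen pass over the concatenated, sentinel-terminated text."""
        text = self._text
        root = _Node(-1, -1)
        root.slink = root
        active_node, active_edge, active_length = root, -1, 0
        remainder = 0

        for i, ch in enumerate(text):
            last_new: Optional[_Node] = None
            remainder += 1
            while remainder > 0:
                if active_length == 0:
                    active_edge = i
                child = active_node.children.get(text[active_edge])
                if child is None:
                    active_node.children[text[active_edge]] = _Node(i, None)
                    if last_new is not None:
                        last_new.slink = active_node
                        last_new = None
                else:
                    edge_len = (child.end if child.end is not None else i + 1) - child.start
                    if active_length >= edge_len:
                        active_node = child
                        active_edge += edge_len
                        active_length -= edge_len
                        continue
                    if text[child.start + active_length] == ch:
                        active_length += 1
                        if last_new is not None:
                            last_new.slink = active_node
                            last_new = None
                        break
                    split = _Node(child.start, child.start + active_length)
                    active_node.children[text[active_edge]] = split
                    split.children[ch] = _Node(i, None)
                    child.start += active_length
                    split.children[text[child.start]] = child
                    if last_new is not None:
                        last_new.slink = split
                    last_new = split
                remainder -= 1
                if active_node is root and active_length > 0:
                    active_length -= 1
                    active_edge = i - remainder + 1
                elif active_node is not root:
                    active_node = active_node.slink
        return root

    def _finalize_full_tree(self) -> None:
        """Annotate leaves with (sequence, position) and trim edges at sentinels.

        The suffix start of a leaf is its edge start minus the string depth of
        its parent; the leaf edge is cut just past the sentinel of the owning
        sequence (safe: internal paths never contain a sentinel).
        """
        text_len = len(self._text)
        starts = self._starts
        stack: list[tuple[_Node, int]] = [(self._root, 0)]
        while stack:
            node, depth = stack.pop()
            for child in node.children.values():
                if child.children:
                    stack.append((child, depth + child.end - child.start))
                else:
                    end = child.end if child.end is not None else text_len
                    suffix_start = child.start - depth
                    seq = bisect_right(starts, suffix_start) - 1
                    sentinel_pos = starts[seq] + self.lengths[seq]
                    child.end = sentinel_pos + 1
                    child.annots.append((seq, suffix_start - starts[seq]))

    def _build_truncated(self, k: int) -> _Node:
        """Compressed trie of the k-prefix of every suffix (plus sentinel).

        Suffixes sharing a k-prefix collapse into one leaf that aggregates all
        their (sequence, position) annotations. Nodes are created only at
        branch points, so path compression holds by construction.
        """
        text = self._text
        root = _Node(-1, -1)
        for seq, seq_start in enumerate(self._starts):
            stop_max = seq_start + self.lengths[seq] + 1  # past the sentinel
            for p in range(seq_start, stop_max):
                stop = min(p + k, stop_max)
                node, pos = root, p
                while True:
                    if pos == stop:
                        node.annots.append((seq, p - seq_start))
                        break
                    child = node.children.get(text[pos])
                    if child is None:
                        leaf = _Node(pos, stop)
                        leaf.annots.append((seq, p - seq_start))
                        node.children[text[pos]] = leaf
                        break
                    # walk the edge, splitting at the first mismatch
                    e, limit = child.start, child.end
                    while pos < stop and e < limit and text[pos] == text[e]:
                        pos += 1
                        e += 1
                    if e == limit:
                        node = child
                        continue
                    if pos == stop:
                        # suffix ends mid-edge: only possible at a sentinel,
                        # which is unique -- cannot happen for k-prefixes that
                        # are proper prefixes of an existing edge. Guarded for
                        # safety: split and annotate the split node.
                        split = _Node(child.start, e)
                        node.children[text[child.start]] = split
                        child.start = e
                        split.children[text[e]] = child
                        split.annots.append((seq, p - seq_start))
                        break
                    split = _Node(child.start, e)
                    node.children[text[child.start]] = split
                    child.start = e
                    split.children[text[e]] = child
                    leaf = _Node(pos, stop)
                    leaf.annots.append((seq, p - seq_start))
                    split.children[text[pos]] = leaf
                    break
        return root

    # ---------------------------------------------------------------- queries

    def _subtree_counts(self, node: _Node, out: np.ndarray) -> None:
        """Accumulate per-sequence annotation counts below (and at) a node."""
        stack = [node]
        while stack:
            v = stack.pop()
            for seq, _ in v.annots:
                out[seq] += 1
            stack.extend(v.children.values())

    def count_word(self, w: str) -> np.ndarray:
        """Per-sequence occurrence counts of word ``w`` (overlaps counted).

        Traverses from the root along the path labeled ``w``; if the
        traversal falls off the tree the word occurs nowhere and an all-zero
        vector is returned. Traversal may end mid-edge, in which case the
        remaining edge characters are compared explicitly.
        """
        if not w:
            raise QueryError("empty query word")
        if set(w) - _ACGT:
            raise QueryError(f"query word {w!r} contains non-ACGT symbols")
        if self.max_depth is not None and len(w) > self.max_depth:
            raise QueryError(
                f"word of length {len(w)} on a tree truncated at depth {self.max_depth}"
            )
        counts = np.zeros(self.n, dtype=np.int64)
        node, pos = self._root, 0
        text = self._text
        while pos < len(w):
            child = node.children.get(w[pos])
            if child is None:
                return counts
            take = min(child.end - child.start, len(w) - pos)
            if text[child.start : child.start + take] != w[pos : pos + take]:
                return counts
            pos += take
            node = child
        self._subtree_counts(node, counts)
        return counts

    def count_all_words_at_depth(self, L: int) -> dict[str, np.ndarray]:
        """Counts of every occurring ACGT word of length ``L``, in one sweep.

        A single depth-bounded DFS collects, at string depth exactly ``L``
        (possibly mid-edge), the aggregated leaf annotations of the locus.
        Paths crossing a sentinel or an ambiguity symbol before depth ``L``
        are pruned, so returned words never span non-ACGT positions.

        Returns a dict mapping each occurring L-word to its length-``n``
        per-sequence count vector; absent words are simply absent.
        """
        if L < 1:
            raise QueryError("L must be >= 1")
        if self.max_depth is not None and L > self.max_depth:
            raise QueryError(
                f"L={L} exceeds truncation depth {self.max_depth}"
            )
        text = self._text
        result: dict[str, np.ndarray] = {}
        stack: list[tuple[_Node, int, str]] = [(self._root, 0, "")]
        while stack:
            node, depth, prefix = stack.pop()
            for child in node.children.values():
                edge = text[child.start : child.end]
                need = L - depth
                if len(edge) >= need:
                    seg = edge[:need]
                    if not (set(seg) - _ACGT):
                        word = prefix + seg
                        vec = np.zeros(self.n, dtype=np.int64)
                        self._subtree_counts(child, vec)
                        result[word] = vec
                elif not (set(edge) - _ACGT):
                    stack.append((child, depth + len(edge), prefix + edge))
        return result

    # ------------------------------------------------------- introspection

    def iter_leaf_annotations(self) -> Iterator[tuple[int, int]]:
        """Yield every (sequence index, suffix start) annotation in the tree."""
        stack = [self._root]
        while stack:
            v = stack.pop()
            yield from v.annots
            stack.extend(v.children.values())

    @property
    def n_leaf_annotations(self) -> int:
        return sum(1 for _ in self.iter_leaf_annotations())

    @property
    def node_count(self) -> int:
        count, stack = 0, [self._root]
        while stack:
            v = stack.pop()
            count += 1
            stack.extend(v.children.values())
        return count

    def iter_leaf_paths(self) -> Iterator[tuple[str, list[tuple[int, int]]]]:
        """Yield (path string from root, annotations) for every annotated node.

        For the full tree the path spells the entire suffix plus its sentinel;
        for a truncated tree it spells the (depth-limited) suffix prefix.
        Sentinels are rendered as ``$``.
        """
        text = self._text
        stack: list[tuple[_Node, str]] = [(self._root, "")]
        while stack:
            node, path = stack.pop()
            if node.annots:
                yield path, list(node.annots)
            for child in node.children.values():
                stack.append((child, path + text[child.start : child.end]))

    def check_invariants(self) -> None:
        """Assert the structural invariants of the generalized suffix tree.

        1. total leaf annotations == sum(m_i + 1);
        2. no two child edges of a node start with the same symbol (holds by
           dict construction; re-checked against edge first characters);
        3. every internal non-root node has >= 2 children;
        4. spelling root -> annotation (i, p) reproduces S_i[p:] + sentinel
           (truncated tree: the first max_depth symbols thereof).

        Raises AssertionError on any violation; intended for tests.
        """
        expected = sum(m + 1 for m in self.lengths)
        assert self.n_leaf_annotations == expected, "annotation count mismatch"

        text = self._text
        stack = [self._root]
        while stack:
            v = stack.pop()
            firsts = [text[c.start] for c in v.children.values()]
            assert len(firsts) == len(set(firsts)), "sibling edges share a first symbol"
            for key, c in v.children.items():
                assert key == text[c.start], "child key != edge first symbol"
                if c.children and not c.annots:
                    assert len(c.children) >= 2, "unary internal node"
                stack.append(c)

        for path, annots in self.iter_leaf_paths():
            for seq, p in annots:
                suffix = self._text[
                    self._starts[seq] + p : self._starts[seq] + self.lengths[seq] + 1
                ]
                if self.max_depth is not None:
                    suffix = suffix[: self.max_depth]
                assert path == suffix, (
                    f"path mismatch for (seq={seq}, pos={p}): {path!r} != {suffix!r}"
                )


def build_gst(seqs: SequenceSet, max_depth: Optional[int] = None) -> GeneralizedSuffixTree:
    """Build the generalized suffix tree of a sequence set.

    Parameters
    ----------
    seqs : SequenceSet
        Non-empty sequences; insertion order fixes sequence indices.
    max_depth : int, optional
        If given, build the depth-``max_depth`` truncated tree instead of the
        full tree. Word queries for ``|w| <= max_depth`` are identical to the
        full tree; memory drops roughly with the truncation depth.
    """
    return GeneralizedSuffixTree(seqs, max_depth=max_depth)
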