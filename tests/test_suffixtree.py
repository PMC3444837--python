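import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lwords.errors import LwordsError, QueryError
from lwords.profile import oracle_counts, word_index
from lwords.suffixtree import build_gst

from conftest import make_set, random_dna


def dense_counts(tree, L, n):
    """Densify a bulk count_all_words_at_depth result over the 4^L columns."""
    out = np.zeros((n, 4 ** L), dtype=np.int64)
    for w, v in tree.count_all_words_at_depth(L).items():
        out[:, word_index(w)] = v
    return out


class TestConstruction:
    def test_single_base_sequence(self):
        tree = build_gst(make_set("A"))
        # suffixes "A$" and "$"
        assert tree.n_leaf_annotations == 2
        tree.check_invariants()

    def test_every_suffix_retrievable_by_path_spelling(self):
        tree = build_gst(make_set("ACGT", "CGT"))
        assert tree.n_leaf_annotations == 5 + 4
        tree.check_invariants()
        # brute-force suffix enumeration equals the annotation set
        seen = set(tree.iter_leaf_annotations())
        expected = {(0, p) for p in range(5)} | {(1, p) for p in range(4)}
        assert seen == expected

    def test_random_sequences_satisfy_all_invariants(self, rng):
        seqs = make_set(*(random_dna(rng, 200) for _ in range(50)),
                        ids=[f"s{i}" for i in range(50)])
        tree = build_gst(seqs)
        tree.check_invariants()
        # empirical linearity of the structure: node count <= 2 * total text
        total = sum(len(r) + 1 for r in seqs)
        assert tree.node_count <= 2 * total

    def test_ambiguity_symbols_allowed_in_tree(self):
        tree = build_gst(make_set("ACNNGT"))
        tree.check_invariants()
        assert tree.count_word("GT").tolist() == [1]

    def test_empty_sequence_rejected(self):
        with pytest.raises(LwordsError, match="at least one record"):
            build_gst(make_set())

    def test_truncated_tree_invariants(self, rng):
        seqs = make_set(*(random_dna(rng, 120) for _ in range(5)),
                        ids=[f"s{i}" for i in range(5)])
        tree = build_gst(seqs, max_depth=4)
        tree.check_invariants()


class TestCountWord:
    def test_overlapping_occurrences(self):
        assert build_gst(make_set("AAAA")).count_word("AA").tolist() == [3]

    def test_per_sequence_counts(self):
        tree = build_gst(make_set("ACGTACGT", "TTTT"))
        assert tree.count_word("CG").tolist() == [2, 0]
        assert tree.count_word("TT").tolist() == [0, 3]

    def test_absent_word_gives_zero_vector(self):
        tree = build_gst(make_set("ACAC"))
        assert tree.count_word("GGGG").tolist() == [0]
        # falls off mid-edge
        assert tree.count_word("ACAG").tolist() == [0]

    @pytest.mark.parametrize("bad", ["", "ACN", "acg", "AC-"])
    def test_invalid_query_rejected(self, bad):
        tree = build_gst(make_set("ACGT"))
        with pytest.raises(QueryError):
            tree.count_word(bad)

    def test_query_deeper_than_truncation_rejected(self):
        tree = build_gst(make_set("ACGTACGT"), max_depth=3)
        with pytest.raises(QueryError, match="truncated"):
            tree.count_word("ACGT")

    def test_word_never_matches_across_sequence_boundary(self):
        # concatenation artifact guard: "GTTT" spans a->b only
        tree = build_gst(make_set("ACGT", "TTTT"))
        assert tree.count_word("GTTT").tolist() == [0, 0]


class TestBulkCounts:
    def test_only_occurring_words_returned(self):
        got = build_gst(make_set("ACGTACGT")).count_all_words_at_depth(2)
        assert {w: v.tolist() for w, v in got.items()} == {
            "AC": [2], "CG": [2], "GT": [2], "TA": [1]
        }

    def test_single_letter_depth(self):
        got = build_gst(make_set("AAAA")).count_all_words_at_depth(1)
        assert {w: v.tolist() for w, v in got.items()} == {"A": [4]}

    def test_bulk_equals_individual_queries(self, rng):
        seqs = make_set(*(random_dna(rng, 60) for _ in range(3)))
        tree = build_gst(seqs)
        from itertools import product

        bulk = tree.count_all_words_at_depth(3)
        for w in ("".join(p) for p in product("ACGT", repeat=3)):
            expect = tree.count_word(w)
            got = bulk.get(w, np.zeros(3, dtype=np.int64))
            assert (got == expect).all(), w

    def test_words_spanning_ambiguity_excluded(self):
        got = build_gst(make_set("ACNGT")).count_all_words_at_depth(2)
        assert {w: v.tolist() for w, v in got.items()} == {"AC": [1], "GT": [1]}


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.text(alphabet="ACGT", min_size=1, max_size=300), min_size=1, max_size=4
    ),
    word=st.text(alphabet="ACGT", min_size=1, max_size=8),
    depth=st.integers(min_value=1, max_value=5),
)
def test_tree_counts_match_sliding_window_oracle(data, word, depth):
    """Suffix-tree word counts equal brute-force sliding-window counts."""
    seqs = make_set(*data, ids=[f"s{i}" for i in range(len(data))])
    tree = build_gst(seqs)
    expect = np.array([oracle_counts(r.residues, len(word)) for r in seqs])
    assert (
        tree.count_word(word) == expect[:, word_index(word)]
    ).all()
    dense = dense_counts(tree, depth, len(data))
    oracle = np.vstack([oracle_counts(r.residues, depth) for r in seqs])
    assert (dense == oracle).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.text(alphabet="ACGTN", min_size=1, max_size=150), min_size=1, max_size=3
    ),
    depth=st.integers(min_value=1, max_value=4),
    extra=st.integers(min_value=0, max_value=3),
)
def test_truncated_tree_equals_full_tree(data, depth, extra):
    """Counts from a depth-truncated tree equal the full tree for |w| <= k."""
    seqs = make_set(*data, ids=[f"s{i}" for i in range(len(data))])
    full = build_gst(seqs)
    trunc = build_gst(seqs, max_depth=depth + extra)
    n = len(data)
    assert (dense_counts(full, depth, n) == dense_counts(trunc, depth, n)).all()


def test_leaf_annotation_conservation(rng):
    seqs = make_set(*(random_dna(rng, int(rng.integers(1, 400)), "ACGTN")
                      for _ in range(8)), ids=[f"s{i}" for i in range(8)])
    for depth in (None, 3):
        tree = build_gst(seqs, max_depth=depth)
        assert tree.n_leaf_annotations == sum(m + 1 for m in seqs.lengths)
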