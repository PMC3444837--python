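# Methods

## The comparison model

`lwords` compares DNA sequences by their *L*-word composition instead of by
alignment. The implicit model is that evolutionarily close sequences share
most of their length-*L* subword spectrum, while substitutions (and, more
destructively, indels that would break an alignment but only locally
perturb word counts) shift a small fraction of it. The method makes no
assumption about positional homology: two sequences of different lengths
are compared through normalized composition vectors only. The cost of this
robustness is that the distance is compositional, not a substitution-rate
estimate: SED values are comparable within one analysis, but are not
branch lengths in substitutions per site.

## Word length selection

The single tunable that matters is the word length *L* (bases). Too small
and profiles saturate (every word occurs many times in every sequence);
too large and profiles become sparse identity fingerprints. The automatic
choice is the lower limit of the optimal resolution range for
word-frequency comparison,

    m = max_i length(S_i),    L = ceil(log4 m),

computed in exact integer arithmetic as the smallest L with 4^L >= m, so
that exact powers of 4 are never bumped up by floating-point noise
(m = 16 gives L = 2). Complete mitochondrial genomes (m ~ 15.5–17 kb) give
L = 8. Any value in the resolution range is defensible, so the CLI accepts
`--word-length` overrides between 1 and the memory guard
(MAX_WORD_LENGTH = 12, i.e. at most 4^12 ≈ 16.8 M profile columns).

## Generalized suffix tree

All counting is served by one generalized suffix tree of the input set.
Construction runs Ukkonen's online algorithm once over the concatenation
S_1 $_1 S_2 $_2 … S_n $_n, where each sentinel $_i is a symbol unique to
sequence i, drawn from the Unicode private-use area and therefore disjoint
from the IUPAC alphabet by construction. Uniqueness of the sentinels gives
the key structural fact: no path from the root to an internal node can
contain a sentinel (two suffixes sharing such a path would imply two
occurrences of the same $_i). Consequently each leaf edge can be trimmed,
after construction, at the sentinel of the sequence owning its suffix,
which converts the suffix tree of the concatenation into the generalized
suffix tree of the set, with exactly sum_i (m_i + 1) leaf annotations
(every suffix of every sequence plus its bare sentinel). Edge labels are
(start, end) references into the shared text, never substring copies.

Word queries walk from the root along the query's characters, comparing
mid-edge characters explicitly, and aggregate the (sequence, position)
annotations below the locus; a traversal that falls off the tree means the
word occurs nowhere. Bulk counting of all words of length L is a single
iterative DFS cut at string depth L. All traversals are loop-based, so
20 kb+ inputs cannot overflow Python's recursion stack.

Ambiguity codes (N, R, Y, …) are kept in the tree as ordinary symbols so
the suffix structure is exact, but the word alphabet is {A,C,G,T}: queries
containing other symbols are rejected, and any length-L window that spans
a non-ACGT symbol is never counted (the DFS prunes at the offending
character). This makes the frequency normalization self-consistent — the
denominator counts exactly the windows that could have been counted.
Whether counts should instead be distributed over the compatible
expansions of an ambiguity code is a modelling choice we deliberately
avoid; skipped windows are a documented limitation. Only the forward
strand is counted; no reverse-complement folding is applied.

### Truncated variant

`build_gst(seqs, max_depth=k)` builds the depth-k truncated tree instead:
a compressed trie of the first k symbols of every suffix, built by direct
insertion in O(total_length × k), in which one truncated leaf aggregates
the annotations of all suffixes sharing a k-prefix. For word lengths
≤ k its counts are identical to the full tree — a property the test suite
checks rather than assumes, which is also why truncation is implemented as
an independent second construction path instead of post-hoc pruning of the
Ukkonen tree. Memory drops roughly by the ratio of k to the mean suffix
length; queries deeper than k raise an error.

## Profiles and distance

The occurrence matrix O (n × t, t = 4^L) is densified over the full
lexicographic word list W_L (A < C < G < T), so matrices from different
datasets with equal L are column-compatible; overlapping occurrences are
counted, giving the window-conservation identity
sum_j O_ij = m_i − L + 1 for pure-ACGT sequences. Rows are normalized to
relative frequencies f_ij = O_ij / sum_j O_ij; a row with no valid L-word
(e.g. an all-N sequence) is an error, not a silent zero row.

The genetic distance is the standard Euclidean distance between profile
rows. For probability vectors its sharp range is [0, sqrt(2)], the maximum
attained by sequences with disjoint word spectra; values are reported
as-is, never clipped or rescaled, because any rescaling would silently
change downstream tree shapes. The matrix is computed once on the upper
triangle (scipy `pdist`) and mirrored, so symmetry is exact.

## Tree and ordination

Neighbor joining follows Saitou & Nei: at each step the pair minimizing
Q(i, j) = (r − 2) d(i, j) − R_i − R_j is joined, with pendant lengths from
the standard two-point formulas and the usual distance reduction. Two
conventions make the output deterministic and well-formed:

* **ties** in Q are broken toward the lexicographically smallest
  (row, column) index pair (row-major argmin);
* **negative** pendant-length estimates (possible on non-additive input)
  are clamped to 0 with the deficit transferred to the sister branch, so
  the joined pair's estimated separation d(i, j) is preserved; at the final
  trifurcation any residual negative is clamped to 0.

The tree is returned unrooted (trifurcating root for n ≥ 3); rooting for
display is the consumer's choice. On additive matrices NJ is exact, which
the tests verify by regenerating random trees from their own path-length
matrices.

The ordination is classical (Torgerson) MDS — double-center −D²/2,
eigendecompose, scale the top-k eigenvectors by the square roots of their
eigenvalues — chosen over iterative stress majorization because it is
deterministic and needs no seed. Negative retained eigenvalues
(non-Euclidean input) are zeroed with a logged warning, collapsing those
axes.

## Synthetic data generator

The simulator exists so every pipeline stage is testable without
downloading genomes. It produces (a) i.i.d. uniform ACGT sequences and
(b) sequences evolved down a known tree: a uniform random root of given
length, and on each branch each site independently substitutes with a
fixed probability to a uniformly chosen different base — a
Jukes–Cantor-like process with equal base frequencies, no indels, no rate
heterogeneity, and a per-branch (not per-unit-length) substitution
probability. Random topologies are drawn by uniformly joining subtrees
until three remain (yielding the unrooted shape NJ itself produces), with
i.i.d. uniform branch lengths on [0.1, 1.0] used only by the additive-
matrix tests, not by the evolution step. A single `numpy.random.Generator`
per call, seeded explicitly, makes identical specifications byte-identical.

What passing the simulation tests shows — and what it does not: recovery
of a 6-taxon topology from 20 kb sequences at 2% per-branch substitution
probability demonstrates that the tree → words → SED → NJ chain preserves
phylogenetic signal under substitution-only divergence with uniform
composition. Real mitochondrial data add indels, strand-asymmetric
composition bias and rate heterogeneity that the generator deliberately
omits; the alignment-free design is motivated by such data, but the tests
quantify performance only under the simulated conditions (6 taxa, 20 kb,
0.02 substitution probability, 10 fixed-seed replicates, ≥ 8/10 required —
a package-chosen threshold).

## Numerical and interface choices

* Word-length selection, counting and distance are exact integer /
  double-precision computations; the only tolerances in the package are
  test tolerances (1e-12 row sums, 1e-9 NJ branch lengths, 1e-8 MDS
  reconstructions).
* PHYLIP output defaults to relaxed labels (full id + single space)
  because accession ids exceed the classic 10-character field;
  `--strict-phylip` restores the classic dialect. Distances print with 6
  significant digits; full double precision is kept internally.
* The Newick writer quotes labels containing metacharacters (internal
  quotes doubled); round-trips are tested against an independent parser.
* The CLI computes everything before writing anything, so a failure
  leaves no partial output files; logs go to stderr only.
* Problem sizes in the test suite (sequences ≤ 500 b for property tests,
  20 kb × 6 taxa × 10 replicates for recovery) were chosen as the smallest
  sizes at which each property is meaningfully exercised.

## Known limitations

* Word counts ignore windows containing ambiguity codes; sequences with
  long N runs lose windows relative to the conservation identity.
* Forward strand only — sequences must be provided in consistent
  orientation.
* SED is compositional: branch lengths on the NJ tree are not
  substitution rates and should not be compared across different L.
* The simulator's no-indel, uniform-composition model understates the
  difficulty of real mitochondrial data (by design; see above).
* The suffix tree is held in memory as Python objects; hundreds of
  megabases are out of scope for this implementation.
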