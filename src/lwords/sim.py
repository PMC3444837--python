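"""Synthetic DNA data: random sequences and evolution down a known tree.

The generator exists so that every pipeline stage is testable without any
downloaded genomes. Two regimes are provided: i.i.d. uniform random
sequences (null input with no phylogenetic signal) and substitution-only
evolution down a known tree, in which each site mutates independently on
each branch with a fixed probability to a uniformly chosen different base
(a Jukes-Cantor-like process with no indels and no rate heterogeneity).

Everything is driven by an explicit integer seed through a single
:class:`numpy.random.Generator` per call; identical arguments give
byte-identical sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skbio import TreeNode

from .errors import LwordsError
from .io import SequenceRecord, SequenceSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one evolution run.

    Attributes
    ----------
    tree : skbio.TreeNode, optional
        Tree to evolve down; if None, a random topology over ``n_taxa``
        leaves is drawn.
    n_taxa : int, optional
        Number of leaves for the random topology (ignored if ``tree`` given).
    root_length : int
        Length of the root sequence, in bases.
    per_branch_sub_prob : float
        Probability, per site and per branch, of a substitution.
    seed : int
        RNG seed; identical specs give identical output.
    """

    root_length: int
    per_branch_sub_prob: float
    seed: int
    tree: Optional[TreeNode] = None
    n_taxa: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_branch_sub_prob <= 1.0:
            raise LwordsError("per_branch_sub_prob must be in [0, 1]")
        if self.root_length < 1:
            raise LwordsError("root_length must be >= 1")
        if self.tree is None and (self.n_taxa is None or self.n_taxa < 2):
            raise LwordsError("give a tree, or n_taxa >= 2")


def random_sequences(n: int, length: int, seed: int) -> SequenceSet:
    """``n`` i.i.d. uniform ACGT sequences of the given length.

    Ids are auto-generated as ``seq1..seqN``.
    """
    if n < 1 or length < 1:
        raise LwordsError("n and length must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        draws = _BASES[rng.integers(0, 4, size=length)]
        records.append(
            SequenceRecord(id=f"seq{i + 1}", description="", residues=draws.tobytes().decode())
        )
    return SequenceSet(tuple(records))


def random_tree(
    n_taxa: int,
    seed: int,
    min_branch: float = 0.1,
    max_branch: float = 1.0,
    labels: Optional[list[str]] = None,
) -> TreeNode:
    """Random unrooted binary topology with uniform branch lengths.

    Built by repeatedly joining two uniformly chosen subtrees until three
    remain, which are attached to the central vertex (so for ``n_taxa >= 3``
    the returned root trifurcates, matching NJ output shape). Branch lengths
    are i.i.d. uniform on ``[min_branch, max_branch]``.
    """
    if n_taxa < 2:
        raise LwordsError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_taxa)]
    nodes = [TreeNode(name=lab) for lab in labels]
    while len(nodes) > min(3, n_taxa):
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(min_branch, max_branch))
        b.length = float(rng.uniform(min_branch, max_branch))
        parent.extend([a, b])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for x in nodes:
        x.length = float(rng.uniform(min_branch, max_branch))
    root.extend(nodes)
    return root


def evolve_on_tree(spec: SimulationSpec) -> tuple[SequenceSet, TreeNode]:
    """Evolve a uniform-random root sequence down a tree.

    On each branch, each site independently substitutes with probability
    ``spec.per_branch_sub_prob`` to one of the three other bases, uniformly
    (branch lengths, if present on the tree, are ignored: the substitution
    probability is constant per branch). Returns the leaf sequences in tree
    tip order together with the true tree.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    if tree is None:
        tree = random_tree(spec.n_taxa, seed=int(rng.integers(0, 2**31 - 1)))

    root_seq = rng.integers(0, 4, size=spec.root_length).astype(np.uint8)
    p = spec.per_branch_sub_prob

    records: list[SequenceRecord] = []
    # iterative pre-order walk carrying each node's evolved sequence
    stack: list[tuple[TreeNode, np.ndarray]] = [(tree, root_seq)]
    while stack:
        node, seq = stack.pop()
        for child in reversed(node.children):
            child_seq = seq.copy()
            if p > 0.0:
                mask = rng.random(spec.root_length) < p
                n_mut = int(mask.sum())
                if n_mut:
                    # shift by 1..3 mod 4: uniform over the three other bases
                    child_seq[mask] = (
                        child_seq[mask] + rng.integers(1, 4, size=n_mut).astype(np.uint8)
                    ) % 4
            stack.append((child, child_seq))
        if node.is_tip():
            records.append(
                SequenceRecord(
                    id=node.name,
                    description="",
                    residues=_BASES[seq].tobytes().decode(),
                )
            )

    tip_order = [t.name for t in tree.tips()]
    by_id = {r.id: r for r in records}
    return SequenceSet(tuple(by_id[name] for name in tip_order)), tree
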