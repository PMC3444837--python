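"""Tree building and ordination from a genetic distance matrix.

Two downstream views of the SED matrix are provided: a neighbor-joining
dendrogram (Saitou & Nei's agglomerative algorithm, exact on additive
matrices) and classical (Torgerson) multidimensional scaling coordinates.

The NJ implementation is deterministic: when several pairs minimize the
Q-criterion the lexicographically smallest (row, column) index pair is
joined, and negative branch-length estimates are clamped to zero with the
deficit transferred to the sister branch so the joined pair's separation is
preserved. The tree is emitted unrooted (trifurcating root for n >= 3); any
rooting for display is the consumer's choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from skbio import DistanceMatrix, TreeNode

from .errors import LwordsError

logger = logging.getLogger(__name__)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Iteratively joins the pair (i, j) minimizing
    ``Q(i,j) = (r - 2) d(i,j) - R_i - R_j`` where ``R_i = sum_k d(i,k)`` and
    r is the current number of nodes; pendant branch lengths follow the
    standard two-point formulas. For n = 2 the single edge is split evenly.

    Returns
    -------
    skbio.TreeNode
        Unrooted tree: the returned root has three children for n >= 3
        (two for n = 2) and every tip is labeled with a sequence id.
    """
    n = dm.shape[0]
    if n < 2:
        raise LwordsError("neighbor joining needs at least 2 taxa")

    d = np.array(dm.data, dtype=np.float64)
    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.ids]

    if n == 2:
        half = d[0, 1] / 2.0
        nodes[0].length = half
        nodes[1].length = half
        root = TreeNode()
        root.extend(nodes)
        return root

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        q = (r - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin scans row-major: first minimum = lexicographically smallest
        # (row, column) pair, making ties deterministic
        i, j = divmod(int(np.argmin(q)), r)
        if i > j:
            i, j = j, i

        dij = d[i, j]
        li = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)

        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])

        du = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(r) if k != i and k != j]
        d_new = np.empty((r - 1, r - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = du[keep]
        d_new[:-1, -1] = du[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]

    # terminal trifurcation: three nodes joined at one internal vertex
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    nodes[0].length, nodes[1].length, nodes[2].length = la, lb, lc
    root = TreeNode()
    root.extend(nodes)
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative pendant length to 0, moving the deficit to its sister.

    Preserves li + lj (the joined pair's estimated separation)."""
    if li < 0.0:
        logger.debug("clamping negative branch length %.3g", li)
        lj += li
        li = 0.0
    if lj < 0.0:
        logger.debug("clamping negative branch length %.3g", lj)
        li += lj
        lj = 0.0
    return li, max(lj, 0.0)


@dataclass(frozen=True)
class MdsEmbedding:
    """Classical-MDS coordinates of a distance matrix.

    Attributes
    ----------
    coordinates : pandas.DataFrame
        One row per sequence (input order), columns ``dim1..dimk``.
    eigenvalues : numpy.ndarray
        The k retained eigenvalues of the double-centered matrix, descending
        (negative values zeroed).
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray

    @property
    def labels(self) -> list[str]:
        return list(self.coordinates.index)


def classical_mds(dm: DistanceMatrix, k: int = 2) -> MdsEmbedding:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers ``-D**2 / 2``, eigendecomposes, and retains the top ``k``
    eigenvalues; coordinates are eigenvectors scaled by the square roots of
    their eigenvalues. Negative retained eigenvalues (non-Euclidean input)
    are zeroed with a logged warning, collapsing those axes.
    """
    n = dm.shape[0]
    if k < 1:
        raise LwordsError("k must be >= 1")
    if k >= n:
        raise LwordsError(f"k={k} requires at least k+1={k + 1} points, got {n}")

    D2 = np.asarray(dm.data, dtype=np.float64) ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * (J @ D2 @ J)
    # top-k eigenpairs of the symmetric Gram matrix, descending
    vals, vecs = eigh(B, subset_by_index=(n - k, n - 1))
    vals, vecs = vals[::-1], vecs[:, ::-1]
    if (vals < -1e-12).any():
        logger.warning(
            "distance matrix is not Euclidean-embeddable in %d dims: "
            "%d negative eigenvalue(s) zeroed", k, int((vals < -1e-12).sum())
        )
    vals = np.clip(vals, 0.0, None)
    coords = vecs * np.sqrt(vals)
    return MdsEmbedding(
        coordinates=pd.DataFrame(
            coords, index=list(dm.ids), columns=[f"dim{i + 1}" for i in range(k)]
        ),
        eigenvalues=vals,
    )
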