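"""Pairwise standard Euclidean distance between L-word frequency profiles.

For sequences X and Y with relative-frequency profiles f_X and f_Y over the
word list W_L, the genetic distance is

    SED(X, Y) = sqrt( sum_{w in W_L} (f_Xw - f_Yw)^2 ).

Because each profile is a probability vector, the sharp upper bound is
sqrt(2) (attained by disjoint compositions); values are reported as-is,
never clipped or rescaled. Only the upper triangle is computed and then
mirrored, so the matrix is exactly symmetric.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .errors import LwordsError


def sed_matrix(F: pd.DataFrame) -> DistanceMatrix:
    """Symmetric n x n standard-Euclidean distance matrix over profile rows.

    Parameters
    ----------
    F : pandas.DataFrame
        Frequency matrix ``F_L`` (rows = sequences, columns = ``W_L``).

    Returns
    -------
    skbio.DistanceMatrix
        Labeled by the row index of ``F`` in order; zero diagonal,
        exactly symmetric.
    """
    if len(F) < 2:
        raise LwordsError("need at least 2 sequences for a distance matrix")
    condensed = pdist(np.asarray(F, dtype=np.float64), metric="euclidean")
    return DistanceMatrix(squareform(condensed), ids=list(F.index))
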