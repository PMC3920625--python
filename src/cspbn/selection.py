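"""Per-gene Markov chains over candidate-function indices.

In a context-sensitive PBN each gene carries a hidden index ``j`` naming
its currently selected update function.  Per step the index is re-drawn
from the candidate distribution ``c`` with switching probability ``q``
and kept otherwise, giving the column-stochastic transition matrix

    P[i, j] = c_i * q + (1 - q) * [i == j]

and the distribution recursion ``d(k+1) = P d(k)``.  With ``q = 0`` the
chain freezes (identity matrix); with ``q = 1`` it is memoryless and
``d(k) = c`` for all ``k >= 1`` (the plain-PBN limit).  For ``q > 0``
``d(k)`` converges geometrically to ``c`` at rate ``1 - q``.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np

from .model import GeneSpec

__all__ = [
    "selection_matrix",
    "propagate_selection",
    "indicator_distribution",
    "is_distribution",
]

#: Simplex tolerance for selection distributions.
DIST_TOL = 1e-9


def selection_matrix(gene: Union[GeneSpec, Sequence[float]],
                     q: float) -> np.ndarray:
    """Build the ``l(i) x l(i)`` column-stochastic switching matrix.

    Entry ``(i_to, j_from)`` is ``c_{i_to} * q + (1 - q)`` on the
    diagonal and ``c_{i_to} * q`` off it, so each column is the
    next-index distribution given the current index.
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"switching probability q={q} outside [0, 1]")
    c = np.asarray(gene.probs if isinstance(gene, GeneSpec) else gene,
                   dtype=float)
    if c.ndim != 1 or c.size < 1:
        raise ValueError("candidate probabilities must be a nonempty vector")
    return q * c[:, None] + (1.0 - q) * np.eye(c.size)


def indicator_distribution(j: int, l: int) -> np.ndarray:
    """Unit-mass distribution on the 1-based candidate index ``j``."""
    if not 1 <= j <= l:
        raise ValueError(f"index {j} outside 1..{l}")
    d = np.zeros(l)
    d[j - 1] = 1.0
    return d


def is_distribution(d: np.ndarray, tol: float = DIST_TOL) -> bool:
    d = np.asarray(d, dtype=float)
    return bool(np.all(d >= -tol) and abs(d.sum() - 1.0) <= tol)


def propagate_selection(d0: np.ndarray, P: np.ndarray,
                        steps: int) -> np.ndarray:
    """Iterate ``d(k+1) = P d(k)``; returns array of shape
    ``(steps + 1, l)`` holding ``d(0) .. d(steps)``.
    """
    d0 = np.asarray(d0, dtype=float)
    P = np.asarray(P, dtype=float)
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if P.ndim != 2 or P.shape[0] != P.shape[1] or P.shape[1] != d0.size:
        raise ValueError(
            f"dimension mismatch: P {P.shape} vs d0 length {d0.size}")
    out = np.empty((steps + 1, d0.size))
    out[0] = d0
    for k in range(steps):
        out[k + 1] = P @ out[k]
    return out
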