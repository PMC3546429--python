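"""Truncated SVD and normalized statistical leverage scores.

The leverage score of column ``j`` at rank ``k`` is

    pi_j = (1/k) * sum_{xi=1..k} (v_j^xi)^2,

the squared mass of the ``j``-th row of the top-``k`` right singular vector
matrix, scaled by ``1/k``.  Up to that scaling these are the diagonal
entries of the hat matrix — the orthogonal projector onto the span of the
top ``k`` singular vectors — which is exactly the leverage diagnostic of
classical regression analysis.  Row scores use the left singular vectors;
this is identical to computing column scores of the transposed matrix and
avoids a second decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrix import DataMatrix, as_data_matrix

#: relative singular-value cutoff below which the trailing singular
#: subspace is numerically arbitrary (rank-deficiency warning threshold)
RANK_DEFICIENT_RTOL = 1e-12


@dataclass
class SVDResult:
    """Singular triplets of a matrix, ordered by non-increasing value.

    ``left_vectors`` is ``m × p``, ``right_vectors`` is ``n × p``; both have
    orthonormal columns.  Signs are fixed so that each right singular
    vector's largest-magnitude entry (ties broken by lowest index) is
    non-negative, making downstream selections run-to-run stable.
    """

    singular_values: np.ndarray
    left_vectors: np.ndarray
    right_vectors: np.ndarray
    p: int


@dataclass
class LeverageResult:
    """Column and row leverage scores of one matrix at rank ``k``."""

    k: int
    column_scores: np.ndarray
    row_scores: np.ndarray
    row_names: list[str]
    col_names: list[str]

    def axis_scores(self, axis: str) -> np.ndarray:
        if axis == "columns":
            return self.column_scores
        if axis == "rows":
            return self.row_scores
        raise ValueError(f"axis must be 'columns' or 'rows', got {axis!r}")

    def axis_names(self, axis: str) -> list[str]:
        return self.col_names if axis == "columns" else self.row_names


def _fix_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # flip each singular pair so the right vector's largest-|.| entry is >= 0;
    # np.argmax returns the first maximum, i.e. ties break at the lowest index
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    return U, Vt


def truncated_svd(A, k: int | None = None) -> SVDResult:
    """Top-``k`` singular triplets of ``A`` (all ``min(m, n)`` are retained).

    Parameters
    ----------
    A
        DataMatrix or array-like with finite entries.
    k
        Rank parameter, ``1 <= k <= min(m, n)``; validates only — the full
        thin SVD is cheap at this package's scale and retaining every
        triplet lets callers re-derive scores at any rank without a second
        decomposition.
    """
    dm = as_data_matrix(A)
    m, n = dm.shape
    p = min(m, n)
    if k is not None and not (1 <= k <= p):
        raise ValueError(f"k must be in [1, {p}], got {k}")
    U, s, Vt = np.linalg.svd(dm.values, full_matrices=False)
    U, Vt = _fix_signs(U, Vt)
    return SVDResult(singular_values=s, left_vectors=U, right_vectors=Vt.T, p=p)


def leverage_scores(svd: SVDResult, k: int,
                    row_names: list[str] | None = None,
                    col_names: list[str] | None = None) -> LeverageResult:
    """Normalized leverage scores at rank ``k`` for both axes.

    Column scores come from the right singular vectors, row scores from the
    left.  Each axis sums to 1 and every score lies in ``[0, 1/k]``.
    """
    if not (1 <= k <= svd.p):
        raise ValueError(f"k must be in [1, {svd.p}], got {k}")
    s = svd.singular_values
    if s[0] > 0 and s[k - 1] < RANK_DEFICIENT_RTOL * s[0]:
        warnings.warn(
            f"sigma_{k} is numerically zero relative to sigma_1; leverage "
            "scores at this rank depend on an arbitrary null-space basis",
            RuntimeWarning, stacklevel=2,
        )
    col = np.sum(svd.right_vectors[:, :k] ** 2, axis=1) / k
    row = np.sum(svd.left_vectors[:, :k] ** 2, axis=1) / k
    m, n = svd.left_vectors.shape[0], svd.right_vectors.shape[0]
    return LeverageResult(
        k=k,
        column_scores=col,
        row_scores=row,
        row_names=list(row_names) if row_names is not None else [str(i + 1) for i in range(m)],
        col_names=list(col_names) if col_names is not None else [str(i + 1) for i in range(n)],
    )


def leverage_for(A, k: int) -> LeverageResult:
    """Convenience: SVD + leverage scores of a DataMatrix in one call."""
    dm = as_data_matrix(A)
    return leverage_scores(truncated_svd(dm, k), k, dm.row_names, dm.col_names)


def sampling_probabilities(scores: np.ndarray, c: float) -> np.ndarray:
    """Importance-sampling probabilities ``p_j = min(1, c * pi_j)``.

    ``sum(p_j)`` is the expected number of kept indices under independent
    Bernoulli draws (at most ``min(c, n)``).
    """
    if c < 0:
        raise ValueError(f"c must be non-negative, got {c}")
    scores = np.asarray(scores, dtype=float)
    return np.minimum(1.0, c * scores)


def default_rank(singular_values: np.ndarray, threshold: float = 0.80) -> int:
    """Smallest ``k`` whose leading singular values sum to more than
    ``threshold`` of the total spectrum sum (strict inequality; sums of
    singular values, not of their squares)."""
    s = np.asarray(singular_values, dtype=float)
    if s.size == 0 or not np.any(s > 0):
        raise ValueError("spectrum has no strictly positive singular value")
    if not (0 <= threshold < 1):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    frac = np.cumsum(s) / np.sum(s)
    return int(np.argmax(frac > threshold)) + 1
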