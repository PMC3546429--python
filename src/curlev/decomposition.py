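"""CUR assembly: C, U, R construction and approximation-error diagnostics.

A CUR decomposition approximates ``A ≈ C U R`` where ``C`` and ``R`` are
*actual* columns and rows of ``A`` (so the factors stay interpretable in
the units of the data) and ``U = C⁺ A R⁺`` is the small linking matrix
that makes the product as close to ``A`` as the chosen rows and columns
allow.  The restricted one-sided form ``A ≈ P_C A = C X`` with
``X = C⁺ A`` keeps only columns; there ``U = C⁺`` is stored and ``X`` is
computed on demand rather than materialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .leverage import LeverageResult, default_rank, leverage_scores, truncated_svd
from .matrix import DataMatrix, as_data_matrix
from .selection import SelectionConfig, SelectionResult, select


def moore_penrose_pinv(M: np.ndarray) -> np.ndarray:
    """Moore–Penrose pseudoinverse via SVD.

    Singular values at or below ``max(m, n) * eps * sigma_max`` are treated
    as zero, so a rank-deficient ``M`` (e.g. a ``C`` holding correlated
    columns) still yields the unique generalized inverse satisfying the
    four Penrose conditions.
    """
    M = np.asarray(M, dtype=float)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.zeros((M.shape[1], M.shape[0]))
    tol = max(M.shape) * np.finfo(float).eps * s[0]
    keep = s > tol
    return (Vt[keep].T / s[keep]) @ U[:, keep].T


@dataclass
class CURResult:
    """Assembled decomposition.

    In full mode ``U`` is ``c × r`` with ``U = C⁺ A R⁺``; in restricted
    mode ``R`` is ``None``, ``U = C⁺`` (``c × m``) and :meth:`getX`
    computes ``X = U A`` lazily.  Columns of ``C`` (rows of ``R``) appear
    in selection order; original positions live in the selection results.
    """

    C: DataMatrix
    U: np.ndarray
    R: DataMatrix | None
    column_selection: SelectionResult
    row_selection: SelectionResult | None
    leverage: LeverageResult | None
    k: int | None
    restricted: bool
    relative_error: float | None = None
    seed: int | None = None
    _A: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def getC(self) -> np.ndarray:
        return self.C.values

    def getU(self) -> np.ndarray:
        return self.U

    def getR(self) -> np.ndarray:
        if self.R is None:
            raise ValueError("restricted decomposition has no R; use getX()")
        return self.R.values

    def getX(self) -> np.ndarray:
        """Restricted-mode coefficient matrix ``X = U A`` (computed on demand)."""
        if not self.restricted:
            raise ValueError("X is defined only for restricted decompositions")
        return self.U @ self._A

    def reconstruct(self) -> np.ndarray:
        if self.restricted:
            return self.C.values @ self.getX()
        return self.C.values @ self.U @ self.R.values


def build_cur(A: DataMatrix, cols: SelectionResult,
              rows: SelectionResult) -> CURResult:
    """Assemble the full decomposition from explicit selections:
    ``C = A[:, cols]``, ``R = A[rows, :]``, ``U = C⁺ A R⁺``."""
    A = as_data_matrix(A)
    if cols.indices.size == 0 or rows.indices.size == 0:
        raise ValueError("selections must be non-empty on both axes")
    C = A.take_cols(cols.indices)
    R = A.take_rows(rows.indices)
    U = moore_penrose_pinv(C.values) @ A.values @ moore_penrose_pinv(R.values)
    return CURResult(C=C, U=U, R=R, column_selection=cols, row_selection=rows,
                     leverage=None, k=None, restricted=False, _A=A.values)


def build_restricted(A: DataMatrix, cols: SelectionResult) -> CURResult:
    """Assemble the one-sided decomposition ``A ≈ C X``, storing ``U = C⁺``."""
    A = as_data_matrix(A)
    if cols.indices.size == 0:
        raise ValueError("column selection must be non-empty")
    C = A.take_cols(cols.indices)
    U = moore_penrose_pinv(C.values)
    return CURResult(C=C, U=U, R=None, column_selection=cols, row_selection=None,
                     leverage=None, k=None, restricted=True, _A=A.values)


def approximation_error(A: DataMatrix, result: CURResult) -> float:
    """Relative Frobenius error ``||A - CUR||_F / ||A||_F``
    (restricted mode: ``||A - CX||_F / ||A||_F``)."""
    A = as_data_matrix(A)
    denom = np.linalg.norm(A.values)
    if denom == 0:
        raise ValueError("approximation error undefined for the zero matrix")
    return float(np.linalg.norm(A.values - result.reconstruct()) / denom)


def cur(A, c: int, r: int | str = "all", *, k: int | None = None,
        method: str = "random", seed: int | None = None,
        compute_error: bool = False) -> CURResult:
    """Top-level entry point: leverage scores, selection, and assembly.

    Parameters
    ----------
    A
        DataMatrix (or array-like) to decompose.
    c, r
        Number of columns and rows to select.  ``r = "all"`` skips row
        selection and returns the restricted form ``A ≈ C X``.
    k
        Rank parameter for the leverage scores.  When omitted, the
        smallest ``k`` whose leading singular values exceed 80% of the
        spectrum sum is used.
    method
        One of ``random``, ``exact.num.random``, ``top.scores``,
        ``ortho.top.scores``, ``highest.ranks``.
    seed
        Seeds the two random strategies; deterministic ones ignore it.
    compute_error
        Attach the relative Frobenius approximation error.
    """
    A = as_data_matrix(A)
    m, n = A.shape
    svd = truncated_svd(A)
    if k is None:
        k = default_rank(svd.singular_values)
    elif not (1 <= k <= min(m, n)):
        raise ValueError(f"k must be in [1, {min(m, n)}], got {k}")
    lev = leverage_scores(svd, k, A.row_names, A.col_names)
    config = SelectionConfig(method=method, c=c, r=r, seed=seed)
    cols, rows = select(A, config, lev)
    result = build_restricted(A, cols) if rows is None else build_cur(A, cols, rows)
    result.leverage = lev
    result.k = k
    result.seed = seed
    if compute_error:
        result.relative_error = approximation_error(A, result)
    return result


def top_leverage(leverage: LeverageResult, count: int,
                 axis: str = "columns") -> list[tuple[str, int, float]]:
    """The ``count`` highest-leverage features of one axis.

    Returns ``(name, position, score)`` triples in descending-score order
    (ties by ascending position); positions are 1-based, ready for
    subsetting the matrix in user-facing tools.
    """
    scores = leverage.axis_scores(axis)
    names = leverage.axis_names(axis)
    if not (1 <= count <= scores.size):
        raise ValueError(f"count must be in [1, {scores.size}], got {count}")
    order = np.argsort(-scores, kind="stable")[:count]
    return [(names[i], int(i) + 1, float(scores[i])) for i in order]
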