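"""Column/row selection strategies driven by leverage scores.

Five strategies are exposed under the names used by the ``method``
parameter of the original toolkit:

``random``
    Independent Bernoulli draw per index with probability
    ``p_j = min(1, c * pi_j)``; the requested count is met only in
    expectation.  This is the default and the strategy backed by the
    relative-error theory of randomized CUR.
``exact.num.random``
    Weighted sampling without replacement of exactly the requested count,
    with weights ``min(1, c * pi_j)``.
``top.scores``
    The indices with the largest leverage scores, deterministically.
``ortho.top.scores``
    Greedy: each pick maximizes leverage times the normalized norm of the
    candidate's component orthogonal to the span of the already-selected
    vectors, so duplicated or highly correlated vectors are not picked
    twice.
``highest.ranks``
    Rank the indices by leverage at every rank parameter ``k' = 1..k``;
    an index's merit is its best rank over all ``k'``.

All tie-breaks are by ascending index, so the three deterministic
strategies are pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .leverage import LeverageResult, leverage_scores, sampling_probabilities, truncated_svd
from .matrix import DataMatrix

METHODS = ("random", "exact.num.random", "top.scores", "ortho.top.scores", "highest.ranks")

_MAX_REDRAWS = 100
_ZERO_TOL = 1e-12


@dataclass
class SelectionConfig:
    """Selection request for one decomposition run.

    ``r`` may be the sentinel string ``"all"``, which skips row selection
    entirely (restricted decomposition).  ``seed`` is required for
    reproducible runs of the two random strategies and ignored by the
    deterministic ones.
    """

    method: str = "random"
    c: int = 0
    r: int | str = "all"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; expected one of {METHODS}"
            )


@dataclass
class SelectionResult:
    """Ordered selected indices for one axis.

    ``indices`` are 0-based positions into the axis (user-facing output,
    e.g. written files, renders them 1-based).  ``filled_from_scores`` is
    set when ``ortho.top.scores`` exhausted the orthogonal complement and
    padded the selection by raw leverage order.
    """

    axis: str
    indices: np.ndarray
    names: list[str]
    scores: np.ndarray
    method: str
    probabilities: np.ndarray | None = None
    filled_from_scores: bool = False


def _result(axis, indices, names_all, scores, method, probabilities=None, filled=False):
    idx = np.asarray(indices, dtype=int)
    return SelectionResult(
        axis=axis,
        indices=idx,
        names=[names_all[i] for i in idx] if names_all is not None else [str(i + 1) for i in idx],
        scores=np.asarray(scores, dtype=float),
        method=method,
        probabilities=None if probabilities is None else np.asarray(probabilities, dtype=float),
        filled_from_scores=filled,
    )


def select_random(probabilities: np.ndarray, seed: int | None,
                  axis: str = "columns", names: list[str] | None = None,
                  scores: np.ndarray | None = None) -> SelectionResult:
    """Keep index ``j`` with probability ``p_j``, independently.

    An empty draw is redrawn (continuing the seeded stream) up to 100
    times; an all-zero probability vector is a selection error.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.any(p > 0):
        raise ValueError("cannot select: all probabilities are zero")
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_REDRAWS):
        keep = rng.random(p.size) < p
        if np.any(keep):
            return _result(axis, np.flatnonzero(keep), names,
                           p if scores is None else scores, "random", probabilities=p)
    raise RuntimeError(f"empty selection after {_MAX_REDRAWS} redraws")


def select_exact_num_random(scores: np.ndarray, count: int, seed: int | None,
                            axis: str = "columns",
                            names: list[str] | None = None) -> SelectionResult:
    """Exactly ``count`` distinct indices, sampled without replacement with
    weights ``min(1, count * pi_j)``."""
    pi = np.asarray(scores, dtype=float)
    if np.any(pi < 0):
        raise ValueError("scores must be non-negative")
    if not (1 <= count <= pi.size):
        raise ValueError(f"count must be in [1, {pi.size}], got {count}")
    w = sampling_probabilities(pi, count)
    n_pos = int(np.count_nonzero(w > 0))
    if count > n_pos:
        raise ValueError(
            f"cannot select {count} indices: only {n_pos} have positive weight"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pi.size, size=count, replace=False, p=w / w.sum())
    return _result(axis, np.sort(chosen), names, pi, "exact.num.random",
                   probabilities=w)


def _descending_order(scores: np.ndarray) -> np.ndarray:
    # stable sort on the negated scores: ties keep ascending-index order
    return np.argsort(-np.asarray(scores, dtype=float), kind="stable")


def select_top_scores(scores: np.ndarray, count: int, axis: str = "columns",
                      names: list[str] | None = None) -> SelectionResult:
    """The ``count`` largest-score indices, in descending-score order."""
    pi = np.asarray(scores, dtype=float)
    if not (1 <= count <= pi.size):
        raise ValueError(f"count must be in [1, {pi.size}], got {count}")
    return _result(axis, _descending_order(pi)[:count], names, pi, "top.scores")


def select_ortho_top_scores(vectors: np.ndarray, scores: np.ndarray, count: int,
                            axis: str = "columns",
                            names: list[str] | None = None) -> SelectionResult:
    """Greedy leverage-times-orthogonality selection.

    ``vectors`` holds the axis vectors as columns (pass ``A`` for columns,
    ``A.T`` for rows).  The first pick is the leverage argmax; each later
    candidate ``j`` is scored ``pi_j * ||(I - P_S) a_j|| / ||a_j||`` with
    ``P_S`` the projector onto the span of the picks so far, so an exact
    duplicate of a selected vector scores 0.  If every remaining candidate
    scores 0 before ``count`` is reached the rest is filled by raw
    leverage order and ``filled_from_scores`` is flagged.
    """
    M = np.asarray(vectors, dtype=float)
    pi = np.asarray(scores, dtype=float)
    n = M.shape[1]
    if pi.size != n:
        raise ValueError("scores length must match the number of vectors")
    if not (1 <= count <= n):
        raise ValueError(f"count must be in [1, {n}], got {count}")

    norms = np.linalg.norm(M, axis=0)
    picked: list[int] = []
    Q = np.empty((M.shape[0], 0))
    filled = False
    remaining = np.ones(n, dtype=bool)
    for step in range(count):
        resid = M[:, remaining] - Q @ (Q.T @ M[:, remaining])
        rnorm = np.linalg.norm(resid, axis=0)
        rem_idx = np.flatnonzero(remaining)
        with np.errstate(invalid="ignore", divide="ignore"):
            cand = np.where(norms[rem_idx] > 0,
                            pi[rem_idx] * rnorm / norms[rem_idx], 0.0)
        if step > 0 and np.max(cand) <= _ZERO_TOL:
            # remaining vectors lie in the selected span: pad by raw leverage
            filled = True
            pad = [int(j) for j in _descending_order(pi) if remaining[j]]
            picked.extend(pad[: count - step])
            break
        # ties (within float jitter of the projection) break to the lowest index
        mx = float(np.max(cand))
        best = int(rem_idx[np.flatnonzero(cand >= mx - 1e-12 * max(mx, 1.0))[0]])
        picked.append(best)
        remaining[best] = False
        q = M[:, best] - Q @ (Q.T @ M[:, best])
        qn = np.linalg.norm(q)
        if qn > _ZERO_TOL:
            Q = np.column_stack([Q, q / qn])
    return _result(axis, picked, names, pi, "ortho.top.scores", filled=filled)


def select_highest_ranks(vectors: np.ndarray, k: int, count: int,
                         axis: str = "columns",
                         names: list[str] | None = None) -> SelectionResult:
    """Best-rank-over-k' selection.

    For each ``k'`` in ``1..k`` the axis indices are ranked by leverage at
    rank ``k'`` (rank 1 = highest score, ties by ascending index).  An
    index's merit is its minimum rank across all ``k'``; the ``count``
    smallest merits win, ties broken by the rank at ``k' = k`` and then by
    ascending index.
    """
    M = np.asarray(vectors, dtype=float)
    n = M.shape[1]
    if not (1 <= k <= min(M.shape)):
        raise ValueError(f"k must be in [1, {min(M.shape)}], got {k}")
    if not (1 <= count <= n):
        raise ValueError(f"count must be in [1, {n}], got {count}")
    svd = truncated_svd(M)
    V = svd.right_vectors
    best_rank = np.full(n, n + 1, dtype=int)
    rank_at_k = np.empty(n, dtype=int)
    sq = V**2
    for kp in range(1, k + 1):
        scores_kp = np.sum(sq[:, :kp], axis=1) / kp
        order = _descending_order(scores_kp)
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(1, n + 1)
        best_rank = np.minimum(best_rank, ranks)
        if kp == k:
            rank_at_k = ranks
    final_scores = np.sum(sq[:, :k], axis=1) / k
    order = np.lexsort((np.arange(n), rank_at_k, best_rank))
    return _result(axis, order[:count], names, final_scores, "highest.ranks")


def select(A: DataMatrix, config: SelectionConfig,
           leverage: LeverageResult) -> tuple[SelectionResult, SelectionResult | None]:
    """Dispatch both axes to the configured strategy.

    Returns ``(columns, rows)``; the rows slot is ``None`` when
    ``config.r == "all"`` (row selection skipped, restricted mode).
    """
    m, n = A.shape
    if not (1 <= config.c <= n):
        raise ValueError(f"c must be in [1, {n}], got {config.c}")
    restricted = config.r == "all"
    if not restricted and not (1 <= int(config.r) <= m):
        raise ValueError(f"r must be in [1, {m}] or 'all', got {config.r}")

    # independent sub-streams per axis so row draws do not recycle column draws
    if config.seed is not None:
        col_seed, row_seed = (int(s.generate_state(1)[0] % 2**31)
                              for s in np.random.SeedSequence(config.seed).spawn(2))
    else:
        col_seed = row_seed = None

    def one_axis(axis: str, count: int, seed) -> SelectionResult:
        scores = leverage.axis_scores(axis)
        names = leverage.axis_names(axis)
        vectors = A.values if axis == "columns" else A.values.T
        if config.method == "random":
            p = sampling_probabilities(scores, count)
            return select_random(p, seed, axis, names, scores)
        if config.method == "exact.num.random":
            return select_exact_num_random(scores, count, seed, axis, names)
        if config.method == "top.scores":
            return select_top_scores(scores, count, axis, names)
        if config.method == "ortho.top.scores":
            return select_ortho_top_scores(vectors, scores, count, axis, names)
        return select_highest_ranks(vectors, leverage.k, count, axis, names)

    cols = one_axis("columns", config.c, col_seed)
    rows = None if restricted else one_axis("rows", int(config.r), row_seed)
    return cols, rows
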