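"""Case-study analytics: PCA scores, group separation, leverage-plot data.

These are the tools used to judge whether a leverage-selected feature
subset discriminates sample groups as well as the full feature set: embed
the samples with PCA, then score the embedding with a separation measure —
for every pair of groups take the median of all cross-group pairwise
Euclidean distances, and sum those medians over the group pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .decomposition import top_leverage
from .leverage import LeverageResult, leverage_scores, truncated_svd
from .matrix import DataMatrix, as_data_matrix
from .selection import (select_exact_num_random, select_highest_ranks,
                        select_ortho_top_scores, select_random,
                        select_top_scores)
from .leverage import sampling_probabilities


@dataclass
class GroupedScores:
    """Sample coordinates plus group labels."""

    points: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.labels = [str(l) for l in self.labels]
        if self.points.shape[0] != len(self.labels):
            raise ValueError("one label per point required")
        if any(not l for l in self.labels):
            raise ValueError("labels must be non-empty")


@dataclass
class LeveragePlotData:
    """Per-feature leverage scores ready for a bar plot, with the
    top-``count`` positions highlighted and the uniform level ``1/n``."""

    names: list[str]
    scores: np.ndarray
    highlighted: np.ndarray
    uniform_level: float


def pca_scores(A, n_components: int, center: bool = True,
               scale: bool = False) -> np.ndarray:
    """Principal-component scores of the samples of an expression matrix.

    ``A`` is features × samples; it is transposed internally so each
    sample becomes a point.  Scores are computed from the SVD of the
    (column-centered, optionally unit-variance-scaled) sample matrix with
    the package's deterministic sign convention.
    """
    dm = as_data_matrix(A)
    X = dm.values.T.copy()  # samples × features
    if not (1 <= n_components <= min(X.shape)):
        raise ValueError(f"n_components must be in [1, {min(X.shape)}]")
    if center:
        X -= X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        if np.any(sd == 0):
            j = int(np.flatnonzero(sd == 0)[0])
            raise ValueError(f"cannot scale constant feature {dm.row_names[j]!r}")
        X /= sd
    svd = truncated_svd(X)
    s = svd.singular_values[:n_components]
    return svd.left_vectors[:, :n_components] * s


def separation_measure(points, labels=None) -> float:
    """Sum over group pairs of the median cross-group Euclidean distance.

    Accepts a :class:`GroupedScores` or ``(points, labels)``.  Fewer than
    two distinct groups → 0.
    """
    if isinstance(points, GroupedScores):
        gs = points
    else:
        if labels is None:
            raise ValueError("labels required when points is an array")
        gs = GroupedScores(points, list(labels))
    if gs.points.shape[0] == 0:
        raise ValueError("at least one point required")
    lab = np.asarray(gs.labels)
    groups = sorted(set(gs.labels))
    total = 0.0
    for g1, g2 in combinations(groups, 2):
        d = cdist(gs.points[lab == g1], gs.points[lab == g2])
        total += float(np.median(d))
    return total


def _select_features(A: DataMatrix, lev: LeverageResult, method: str,
                     count: int, seed):
    """Row (feature) selection for the sweep, dispatched by method name."""
    scores = lev.row_scores
    names = lev.row_names
    if method == "random":
        p = sampling_probabilities(scores, count)
        return select_random(p, seed, "rows", names, scores)
    if method == "exact.num.random":
        return select_exact_num_random(scores, count, seed, "rows", names)
    if method == "top.scores":
        return select_top_scores(scores, count, "rows", names)
    if method == "ortho.top.scores":
        return select_ortho_top_scores(A.values.T, scores, count, "rows", names)
    if method == "highest.ranks":
        return select_highest_ranks(A.values.T, lev.k, count, "rows", names)
    raise ValueError(f"unknown method {method!r}")


def separation_sweep(A, labels, k_values, c_values, n_components: int = 2,
                     method: str = "top.scores",
                     seed: int | None = None) -> pd.DataFrame:
    """Separation of the groups as a function of (k, number of features).

    For each grid point (k, c): compute row leverage scores at rank ``k``,
    keep ``c`` features with the configured method, embed the samples with
    ``n_components`` PCs and evaluate :func:`separation_measure`.  One
    extra baseline row holds the all-features value, so the result has
    ``len(k_values) * len(c_values) + 1`` rows (columns: k, c,
    separation, is_baseline).
    """
    dm = as_data_matrix(A)
    labels = [str(l) for l in labels]
    if len(labels) != dm.shape[1]:
        raise ValueError("one label per sample (column) required")
    svd = truncated_svd(dm)
    rows = []
    baseline = separation_measure(pca_scores(dm, n_components), labels)
    rows.append({"k": np.nan, "c": dm.shape[0], "separation": baseline,
                 "is_baseline": True})
    ss = np.random.SeedSequence(seed) if seed is not None else None
    for k in k_values:
        lev = leverage_scores(svd, int(k), dm.row_names, dm.col_names)
        for c in c_values:
            sub_seed = (int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
                        if ss is not None else None)
            sel = _select_features(dm, lev, method, int(c), sub_seed)
            reduced = dm.take_rows(sel.indices)
            sep = separation_measure(pca_scores(reduced, n_components), labels)
            rows.append({"k": int(k), "c": int(c), "separation": sep,
                         "is_baseline": False})
    return pd.DataFrame(rows, columns=["k", "c", "separation", "is_baseline"])


def leverage_plot_data(leverage: LeverageResult, axis: str = "columns",
                       top_count: int = 1) -> LeveragePlotData:
    """Scores in original feature order with the top-``count`` highlighted
    and the uniform level ``1/n`` for reference."""
    scores = leverage.axis_scores(axis)
    top = top_leverage(leverage, top_count, axis)
    return LeveragePlotData(
        names=list(leverage.axis_names(axis)),
        scores=scores.copy(),
        highlighted=np.array([pos - 1 for _, pos, _ in top], dtype=int),
        uniform_level=1.0 / scores.size,
    )


def plot_leverage(data: LeveragePlotData, path: str | None = None):
    """Thin optional rendering of :class:`LeveragePlotData` (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    x = np.arange(data.scores.size)
    ax.bar(x, data.scores, color="0.6", width=1.0)
    ax.plot(data.highlighted, data.scores[data.highlighted], "k.", ms=4)
    ax.axhline(data.uniform_level, color="r", lw=0.8)
    ax.set_xlabel("feature index")
    ax.set_ylabel("leverage score")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
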