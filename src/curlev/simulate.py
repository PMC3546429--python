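"""Synthetic fixtures: low-rank-plus-noise and grouped-expression matrices.

Two generators cover the structures the toolkit is meant to find:

* :func:`generate_low_rank` — a planted low-rank signal (product of
  Gaussian factors) with optional additive Gaussian noise and optional
  extra columns orthogonal to the signal span.  An orthogonal planted
  column carries a singular direction of its own, so at rank
  ``rank + n_planted`` its leverage score is exactly ``1/k`` — the
  maximum — which is what makes it recoverable by ``top.scores``.

* :func:`generate_grouped_expression` — a genes × samples matrix shaped
  like a small microarray study: unit-scale Gaussian baseline, 2–4 sample
  groups, and a handful of informative genes whose group means are
  shifted.  Defaults mirror a 31-sample, 3-group tumor panel with 27
  informative genes out of a few hundred, the geometry of the classic
  soft-tissue-tumor discrimination benchmark at reduced feature count.

All randomness flows through one seeded :class:`numpy.random.Generator`;
the signal (factors, planted columns, group shifts) is drawn before the
noise, so two specs differing only in ``noise_sd`` share their signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import DataMatrix


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic generators.

    m, n
        Matrix dimensions (features × samples for the expression
        generator, where n is derived from ``group_sizes``).
    rank
        Planted signal rank of the low-rank generator.
    noise_sd
        Standard deviation of the additive Gaussian noise (also the
        baseline expression scale of the grouped generator).
    n_planted
        Extra columns orthogonal to the signal span.
    group_sizes
        Samples per group; defaults to 3 groups of 31 samples total.
    n_informative
        Genes carrying group-specific mean shifts (first rows).
    effect
        Between-group mean difference of an informative gene, in
        baseline-noise standard deviations.  The default 5 makes the
        planted genes unambiguous class markers (a 2–3 fold change on a
        log2 scale with typical within-group spread), as in the tumor
        panels this generator emulates.
    seed
        Generator seed; identical specs produce identical matrices.
    """

    m: int = 500
    n: int = 31
    rank: int = 5
    noise_sd: float = 1.0
    n_planted: int = 0
    group_sizes: tuple[int, ...] = (11, 10, 10)
    n_informative: int = 27
    effect: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g < 1 for g in self.group_sizes):
            raise ValueError("every group needs at least one sample")


def generate_low_rank(spec: SyntheticSpec) -> DataMatrix:
    """Low-rank Gaussian signal + noise, with optional planted columns.

    The planted columns are unit vectors orthogonal to the signal column
    span (and to each other), scaled to the mean signal-column norm, and
    appended after the ``n`` signal columns under names ``planted1``,
    ``planted2``, ...  Noise (if any) is added to every entry last.
    """
    if spec.rank > min(spec.m, spec.n):
        raise ValueError("rank must not exceed min(m, n)")
    rng = np.random.default_rng(spec.seed)
    G1 = rng.normal(size=(spec.m, spec.rank))
    G2 = rng.normal(size=(spec.rank, spec.n))
    signal = G1 @ G2

    planted_cols = []
    if spec.n_planted > 0:
        if spec.rank + spec.n_planted > spec.m:
            raise ValueError("not enough dimensions to plant orthogonal columns")
        Q, _ = np.linalg.qr(G1)
        scale = float(np.mean(np.linalg.norm(signal, axis=0)))
        for _ in range(spec.n_planted):
            v = rng.normal(size=spec.m)
            v -= Q @ (Q.T @ v)
            v /= np.linalg.norm(v)
            planted_cols.append(scale * v)
            Q = np.column_stack([Q, v])
    values = (np.column_stack([signal] + planted_cols)
              if planted_cols else signal)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)

    col_names = [f"c{j + 1}" for j in range(spec.n)] + [
        f"planted{j + 1}" for j in range(spec.n_planted)
    ]
    row_names = [f"r{i + 1}" for i in range(spec.m)]
    return DataMatrix(values, row_names, col_names)


def generate_grouped_expression(spec: SyntheticSpec) -> tuple[DataMatrix, list[str]]:
    """Grouped expression matrix (features × samples) plus sample labels.

    The first ``n_informative`` features are informative: feature ``i`` is
    up-shifted in group ``i mod g`` relative to the other groups by
    ``effect``, cycling so every group receives discriminating genes.  The
    shift pattern is mean-centered across samples, so the planted
    between-group structure spans exactly ``g - 1`` dimensions — the rank
    at which leverage scores are expected to recover the informative
    genes.  The remaining features are pure baseline noise.
    """
    if spec.n_informative > spec.m:
        raise ValueError("n_informative must not exceed the feature count")
    rng = np.random.default_rng(spec.seed)
    sizes = list(spec.group_sizes)
    g = len(sizes)
    n_samples = int(sum(sizes))
    labels = [f"grp{gi + 1}" for gi, size in enumerate(sizes) for _ in range(size)]
    bounds = np.concatenate([[0], np.cumsum(sizes)])

    shifts = np.zeros((spec.m, n_samples))
    for i in range(spec.n_informative):
        gi = i % g
        w = sizes[gi] / n_samples
        shifts[i, :] = -spec.effect * w
        shifts[i, bounds[gi]:bounds[gi + 1]] = spec.effect * (1 - w)
    values = shifts + rng.normal(0.0, spec.noise_sd, size=(spec.m, n_samples)) \
        if spec.noise_sd > 0 else shifts.copy()

    row_names = [f"g{i + 1}" for i in range(spec.m)]
    col_names = [f"s{j + 1}" for j in range(n_samples)]
    return DataMatrix(values, row_names, col_names), labels
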