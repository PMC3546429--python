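# Methods

## Model and procedure

The package computes low-rank approximations `A ≈ C U R` in which `C`
(`m × c`) and `R` (`r × n`) are actual columns and rows of the data
matrix `A` and `U = C⁺ A R⁺` minimizes the Frobenius reconstruction
error given those selections. The one-sided restricted form
`A ≈ P_C A = C X`, `X = C⁺ A`, keeps only columns; `P_C` is the
orthogonal projector onto `span(C)`.

Column importance is the normalized statistical leverage score at rank
`k`: `π_j = (1/k) Σ_{ξ≤k} (v_jξ)²`, the scaled diagonal of the hat
matrix `V_k V_kᵀ`. Row scores use the left singular vectors, which is
algebraically identical to running the column procedure on `Aᵀ` but
costs no second SVD. Scores per axis sum to 1 and are bounded by `1/k`
(row norms of an orthonormal-column matrix).

Assumptions: `A` is dense, finite, and small enough for a thin dense
SVD (the package targets expression-matrix scale, up to a few thousand
by a few thousand; no sketched or sparse paths are provided). Leverage
at rank `k` is only meaningful when `σ_k` is not numerically zero; when
`σ_k < 1e-12·σ_1` the scores depend on an arbitrary null-space basis
and a `RuntimeWarning` is emitted rather than an error, since
rank-deficient inputs are legitimate (e.g. noiseless synthetic data).

## Parameters that matter

- `k` (rank parameter, dimensionless): governs which structure the
  selection targets. Default: the smallest `k` whose top singular
  values sum to **strictly more than 80%** of the total spectrum sum —
  sums of singular values, not their squares, and a strict inequality.
  The threshold is exposed (`default_rank(..., threshold=)`).
- `c`, `r` (selected column/row counts): explicit input parameters;
  the package does not size them from an error target. `r = "all"`
  skips row selection entirely and returns the restricted form. The
  multiplication `X = U A` is never performed eagerly; `getX()`
  computes it on demand.
- `method`: `random` draws index `j` independently with
  `p_j = min{1, c·π_j}`, so only the *expected* count equals `c`; an
  empty draw is redrawn from the continuing stream up to 100 times
  before erroring, rather than silently returning nothing.
  `exact.num.random` guarantees the count via weighted sampling without
  replacement with the same weights. The three deterministic variants
  are pure functions of `(A, k, count)` with all ties broken by
  ascending index.
- `seed`: drives every random strategy through
  `numpy.random.Generator`; the column and row axes receive independent
  child streams of one `SeedSequence`, so a logged seed reproduces a
  run bit-for-bit.

## Concretized strategies

Two strategies are specified only behaviorally in the R original, so
their iteration rules are this package's own design:

- `ortho.top.scores`: greedy; the first pick is the leverage argmax,
  and each subsequent candidate `j` is scored
  `π_j · ‖(I − P_S) a_j‖ / ‖a_j‖` with `P_S` the projector onto the
  already-selected span (zero-norm vectors score 0). This directly
  encodes "leverage and orthogonality to the selected subspace", and
  collapses to `top.scores` when the data vectors are mutually
  orthogonal. If every remaining candidate lies in the selected span,
  the remainder is filled by raw leverage order and the result carries
  a `filled_from_scores` flag. Tie comparisons use a `1e-12` relative
  tolerance because the projector arithmetic jitters at the last ulp.
- `highest.ranks`: for every `k′ = 1..k` rank the indices by leverage
  at rank `k′`; an index's merit is its best (minimum) rank across the
  `k′` values, ties broken by the rank at `k′ = k`, then by index.

`exact.num.random` uses weights `min(1, count·π_j)`; the mechanism
(without-replacement importance sampling) is likewise a design choice —
it preserves the importance weighting while guaranteeing the count.

No `1/√(c·p_j)` rescaling is applied anywhere: the factors are actual
data columns, and rescaling would break the interpretability that is
the method's point.

## Numerical choices

- SVD sign convention: each right singular vector is flipped so its
  largest-magnitude entry (ties → lowest index) is non-negative.
  Leverage scores are sign-invariant; the convention exists so that
  selections and PCA scores are bit-stable across runs.
- Pseudoinverse: SVD-based, inverting only singular values above
  `max(m, n) · eps · σ_max`. The textbook formula assumes full-rank
  `C`; a real `C` can be rank-deficient when correlated columns are
  selected, and the cutoff handles that case.
- Approximation error: relative Frobenius norm
  `‖A − CUR‖_F / ‖A‖_F` (the norm of the underlying CUR theory);
  undefined (error) for `‖A‖_F = 0`. The absolute norm is recoverable
  as `error · ‖A‖_F`.
- Median convention (separation measure): midpoint of the two central
  order statistics for even counts. Fewer than two groups → 0.
- PCA: samples are columns of the input and are transposed internally;
  features are centered by default and not scaled (expression analyses
  conventionally center only; scaling is available and errors on
  constant features). Scores come from the centered SVD under the same
  sign convention.
- User-facing indices (files, `top_leverage`, CLI logs) are 1-based,
  matching the R heritage; in-memory `SelectionResult.indices` are
  0-based numpy positions.

## Synthetic data: what it emulates and what it does not

`generate_low_rank` draws a Gaussian factor product of chosen rank,
optionally appends columns orthogonal to the signal span (scaled to the
mean signal-column norm), then adds i.i.d. Gaussian noise. An
orthogonal planted column owns a singular direction of its own, so at
`k = rank + n_planted` its leverage is exactly the `1/k` maximum — the
construction guarantees recoverability and is used to verify that the
selection machinery finds it.

`generate_grouped_expression` emulates the geometry of a small
microarray study: 31 samples in 3 groups by default, unit-variance
Gaussian baseline, and 27 informative genes out of 500 whose group
means differ by `effect = 5` baseline standard deviations (strong,
unambiguous class markers, a 2–3 fold change at typical log-scale
spread). The shift patterns are mean-centered across samples, so the
planted between-group structure spans exactly `g − 1` dimensions — the
rank at which leverage scores are expected to find the markers. Signal
is drawn before noise, so specs differing only in `noise_sd` share
their planted structure.

What the generators do **not** reproduce: gene–gene correlation blocks,
heavy-tailed and heteroscedastic probe noise, batch effects, and the
sheer feature count of real arrays (thousands of genes). Passing tests
therefore demonstrate that the algorithms recover the structure they
are designed to see under clean planted conditions — not that any
particular real dataset will yield a specific marker panel. The real
tumor and compendium datasets the method is known for are external
downloads and deliberately not vendored; `read_matrix` accepts a
user-downloaded copy in plain TSV.

## Problem sizes

Tests and the acceptance script run on matrices between `5 × 5` and
`500 × 31`, 10–20 replicate seeds for stochastic properties, and
1000–2000 draws for the sampling contracts — sizes at which every
property being checked is already exercised and the whole suite runs in
seconds on one core.

## Known limitations

- Dense SVD only; no randomized/sketched path for very large matrices.
- `ortho.top.scores` and `highest.ranks` are faithful concretizations
  of behaviorally-described strategies; other readings exist and may
  order picks differently on data with near-ties.
- The default-`k` rule reads "more than 80%" as a strict inequality;
  spectra engineered to hit the threshold exactly will take the next
  `k`.
- The separation sweep computes distances in `n_components` principal
  components (default 2); the measure depends on that choice and it is
  exposed as a parameter.
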