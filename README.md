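# curlev

CUR matrix decomposition and leverage-score feature selection for
expression matrices.

## The problem

Dimensionality reduction of large expression matrices usually means PCA
or the SVD. The singular vectors it produces are optimal summaries, but
they are linear combinations of up to *all* genes — a downstream analyst
cannot point at a principal component and name the probes behind it. CUR
decomposition addresses this by building the low-rank approximation out
of **actual columns and rows of the data**:

```
A ≈ C · U · R
```

where `A` is the `m × n` data matrix, `C` holds `c` actual columns of
`A`, `R` holds `r` actual rows, and `U = C⁺ A R⁺` is the small linking
matrix (`⁺` is the Moore–Penrose pseudoinverse). Because `C` and `R` are
real data vectors, the factorization is interpretable: the selected
columns/rows *are* the most informative samples and genes.

Which columns to keep is decided by the **normalized statistical
leverage scores**. With `v^1, …, v^k` the top `k` right singular vectors
of `A`,

```
π_j = (1/k) · Σ_{ξ=1..k} (v_jξ)²        j = 1, …, n
```

Up to the `1/k` scaling these are the diagonal entries of the hat matrix
(the projector onto the top-`k` right singular subspace) — the classical
influence diagnostic of regression analysis. Scores sum to 1 per axis,
so they double as an importance-sampling distribution: the randomized
selection keeps column `j` with probability `p_j = min{1, c·π_j}`.

The package provides:

* leverage scores for both axes at any rank `k`, with an automatic `k`
  (smallest `k` whose top singular values exceed 80% of the spectrum
  sum) when none is given;
* five selection strategies — `random` (the theory-backed default),
  `exact.num.random`, `top.scores`, `ortho.top.scores`,
  `highest.ranks`;
* full (`C, U, R`) and restricted (`A ≈ C X`, `X = C⁺ A`) assembly with
  relative Frobenius error diagnostics;
* case-study analytics: PCA sample scores, a group-separation measure
  (sum over group pairs of the median cross-group distance), and a
  `(k, c)` separation sweep;
* delimited-matrix I/O, leverage-plot data, synthetic generators, and a
  `curlev` command line.

## Worked example

Select marker genes from a synthetic 3-group expression study
(500 genes × 31 samples, 27 planted markers):

```python
from curlev import (SyntheticSpec, generate_grouped_expression, cur,
                    top_leverage, separation_sweep)

spec = SyntheticSpec(seed=0)            # 500 genes x 31 samples, 3 groups
expr, groups = generate_grouped_expression(spec)

res = cur(expr, c=5, r="all", k=2, method="top.scores", compute_error=True)
print(f"rank parameter k = {res.k}")
print(f"restricted CUR relative error = {res.relative_error:.3f}")

print("top 5 leverage genes (rows):")
for name, pos, score in top_leverage(res.leverage, 5, "rows"):
    print(f"  {name:>5}  position {pos:>3}  leverage {score:.4f}")

table = separation_sweep(expr, groups, k_values=[2], c_values=[27])
print(table.to_string(index=False))
```

prints

```
rank parameter k = 2
restricted CUR relative error = 0.855
top 5 leverage genes (rows):
     g2  position   2  leverage 0.0395
     g5  position   5  leverage 0.0387
    g19  position  19  leverage 0.0373
    g22  position  22  leverage 0.0346
     g1  position   1  leverage 0.0342
  k   c  separation  is_baseline
NaN 500   69.113565         True
2.0  27   63.431020        False
```

All five top-leverage genes are planted markers (the informative genes
occupy positions 1–27 in this generator). The sweep shows that the 27
selected genes — 5% of the features — retain 92% of the all-gene group
separation (63.4 vs 69.1). The uniform leverage level here is
`1/500 = 0.002`; the markers score ~20× above it.

The same pipeline from the shell:

```sh
curlev simulate --kind grouped --seed 0 --output-prefix fix
curlev decompose --input fix_matrix.tsv --c 5 --restricted \
       --method top.scores --error --output-prefix run
curlev sweep --input fix_matrix.tsv --labels fix_labels.tsv \
       --k-values 2,3 --c-values 10,27,100 --output sweep.tsv
```

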