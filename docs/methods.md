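# Methods

## Model

Let `A` be an `m × n` real matrix (samples × features) with SVD
`A = UΣVᵀ` and numerical rank `ρ`.  Writing `V̄` for the right singular
vectors `v_{ρ+1}, …, v_n`, the signature matrix

```
S = I − A†A = V̄V̄ᵀ
```

is the orthogonal projector onto `null(A)`: symmetric, idempotent,
`trace(S) = n − ρ`, diagonal in `[0, 1]`, and `AS = 0`.  A set of columns
that is linearly dependent within itself and independent of all other
columns ("a cluster") corresponds to an invariant block of `S`: entries
pairing features from different clusters are exactly zero, and the graph on
the nonzero entries restricted to one cluster is connected.  Connected
components of the thresholded `S`-graph therefore recover the clusters.

For a labeled dataset `D = [A | b]` the same construction applied to `D`
yields a last row whose entry at feature `i` is nonzero exactly when `F_i`
shares a dependency cluster with the label; its magnitude serves as the
feature's relevance score.  The minimum-norm least-squares solution
`x = A†b` gives a complementary relevance measure: `x_i = 0` for every
feature outside the label's cluster structure.

## Pipeline and parameters

| parameter | default | meaning |
|---|---|---|
| `th_irr` | 3 | mean-scaled soft threshold of both irrelevance steps (dimensionless) |
| `th_red` | 4 | mean-scaled cutoff zeroing weak `S` entries before graph building (7 suits image-like data) |
| `alpha`  | 50 | maximum cluster size; larger clusters are split into chunks |
| `beta`   | 5 | relevance-ranked candidates per (sub-)cluster entering the MI comparison |
| `k`      | 50 | length of the final MI-descending selection |
| `mi_bins` | "sturges" | equal-width bins for MI: `⌈log2 m⌉ + 1` |

Step 1 keeps features with `|x_i| ≥ mean(|x|)·th_irr`.  Step 2, applied to
the reduced matrix, zeroes label-row scores below `mean·th_irr` and keeps
the descending-sorted prefix with score `≥ mean·(th_irr + 1)`.  Both raw
quantities (`|x_i|`, `|S_D[i, n+1]|`) are scale-dependent, so the mean-scaled
formulation keeps one dimensionless threshold meaningful across datasets.
Because the step-2 cutoff always sits at or above the mean score, the
filter is intentionally aggressive when only a handful of comparably
relevant features remain (as in the small worked examples); permissive
values (`th_irr ≤ 0.5`) are appropriate for fixtures with tens of features,
while the defaults are tuned to the thousands-of-features regime the method
targets, where irrelevant features dominate the mean.

Mutual information uses plug-in histogram estimates in base 2.  The base
only rescales MI and never reorders candidates, so the representative
choice is base-invariant.  Continuous label vectors (planted regression
labels) are discretized with the same equal-width policy before MI;
integer class codes pass through unchanged.  All ties — BFS roots, equal
relevance, equal MI — break toward the lower original column index, making
every run bit-reproducible.

One representative is taken per sub-cluster after `alpha`-splitting (not
per original component): after splitting, each chunk is a set of mutually
redundant features of comparable relevance, and capping the MI evaluations
at `beta` per chunk bounds cost on the huge clusters real expression data
produces.

## Numerical choices

- Rank/null-space cutoff: `max(m, n) · eps · σ_max`, shared by
  `numerical_rank`, `signature_matrix` and `minnorm_weights` so downstream
  block structure is consistent.  On planted data any standard cutoff gives
  the same rank because the dependencies are exact.
- `S` is computed from the SVD (`V̄V̄ᵀ`), never via an explicit
  pseudo-inverse, avoiding the inversion of `AAᵀ` for rank-deficient `A`.
  For wide matrices (`m < n`) the thin SVD omits `n − min(m, n)` null
  directions; they are restored as `I − VVᵀ`.
- Projector identities are tested at tolerance `1e−8` for matrices up to
  ~10⁴ entries.
- Rounding to 2 or 4 decimals happens only in displays and tests, never in
  the pipeline.

## Synthetic data

`generate_planted_matrix` draws free columns i.i.d. standard normal
(seeded) and solves for one pivot column per relation — lowest-index
nonzero-coefficient feature not already a pivot — through a joint linear
solve of the pivot block.  The joint solve makes mutually referencing
relations (pivot `F5` needing `F10` and vice versa, as in the reference
set) well-defined; errors arise only when a relation has no unassigned
feature left or the pivot submatrix is singular.  With `noise_sd > 0` the
pivot columns are perturbed, degrading the exact dependencies so threshold
behavior can be studied.  Labels are planted as exact linear combinations
and optionally discretized by equal-frequency quantile binning, which keeps
class counts within one of each other.

`projection_oracle` builds the projector onto the span of the relation
vectors by QR — an SVD-free route that must agree entrywise with
`signature_matrix` on noiseless planted data (tested to `1e−6` across
random specs).  `minimal_relations` column-reduces the relation vectors
restricted to one cluster to the canonical form with leading coefficient
−1 on the lowest-index pivots, giving the cluster's minimal dependence
relations.

What the simulator does *not* emulate: expression-scale marginals,
batch effects, missingness, or the approximate (rather than exact)
collinearity of real co-regulated genes.  Passing tests on planted data
demonstrate the algebraic machinery — exact cluster recovery, filter
behavior, representative choice — not robustness to biological noise;
`noise_sd` probes the transition away from exactness but real-data
validation is out of scope here.

## Evaluation harness

`evaluate_cv` runs repeated stratified k-fold cross-validation (defaults
5 folds × 2 repeats): selection is fitted on the training folds only, and a
caller-supplied fit/predict classifier (default: random forest with library
defaults) is scored on the held-out fold for every prefix length `t` of the
selected list.  The classifier is plumbing for assessing a selection, not
part of the method.  Test problem sizes throughout the suite are kept at
`m ≤ 100`, `n ≤ 200`, where every stage's behavior is already fully
exercised and the planted oracles are exact.

## Known limitations

- The two filtering steps assume irrelevant features dominate: on inputs
  where most features are relevant, mean-scaled cutoffs with the default
  `th_irr` can discard everything (the pipeline then reports "no relevant
  features", exit code 4, rather than guessing).
- With `m < n` and a generic label, `b` lies in the column space and the
  weight vector spreads over many features; relevance screening then relies
  on relative magnitudes rather than exact zeros.
- Histogram MI is biased upward for small `m`; with the Sturges policy this
  bias is shared by all candidates of a cluster and rarely changes the
  argmax, but absolute MI values should not be over-interpreted.
- `S` is dense `n × n`; memory is the practical bound for `n` beyond a few
  tens of thousands of features.
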