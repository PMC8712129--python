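# Methods

## Problem setting

A labeled expression matrix: n samples (tens) by M genes (hundreds to
tens of thousands), continuous intensities, one binary class label per
sample. The goal is a small gene subset that supports accurate
classification. Everything below treats selection as minimization of
objective vectors under Pareto dominance.

## Search engine

Differential evolution over [0,1]^M with an external archive.

* **Encoding / decoding.** Continuous position x; gene j is in the
  subset iff x_j ≥ λ. The comparison is ≥ (not >): at random
  initialization the difference has measure zero, but the choice is
  pinned for reproducibility. An empty decode selects the argmax
  component instead, so every individual stays evaluable and |S| ≥ 1.
* **Archive.** Capacity N_a; a candidate enters if the archive is empty,
  if it is nondominated and there is room, or if it dominates members
  (which are then purged). A full archive accepts a mutually
  nondominated candidate by evicting the member with the smallest
  crowding distance computed over the enlarged set; ties evict the
  earliest-inserted member, for determinism. Candidates dominated by any
  member are rejected, as are exact positional duplicates of a member —
  without that rule a plateau objective floods the archive with clones
  of one solution.
* **Crowding distance** follows the NSGA-II convention: per objective,
  sort; extremes get +∞; interior members accumulate the normalized gap
  between their neighbors; a zero-range objective contributes nothing;
  fronts of ≤ 2 points are all-infinite.
* **Mutation** V = X_arc + F·(X_r2 − X_r3): the base is uniform over the
  archive, r2 ≠ r3 ≠ i are population indices drawn without
  replacement. The archive base may coincide with a population member;
  that is allowed. Binomial crossover with a forced component; trials
  are clipped back into [0,1].
* **Selection.** Trial vs. target by dominance; a mutually nondominated
  trial is offered to the archive and replaces its target exactly when
  the archive accepted it. This keeps "successful replacement"
  well-defined for parameter adaptation and routes every promising trial
  through the archive. The rule is isolated in `mo_select` so
  alternative orderings can be swapped in.
* **Parameter control.** Per individual per iteration, F ~ N(0.5, 0.3²)
  truncated to (0,2] by resampling and Cr ~ N(Cr_m, 0.1²) truncated to
  [0,1] by resampling. Cr_m starts at 0.5; Cr values of accepted trials
  enter a pool, and at the end of each iteration Cr_m becomes the pool
  median (unchanged if the pool is empty). Truncation by resampling
  rather than clipping is deliberate: clipping concentrates a point mass
  at the boundary, and once the success median reaches 0 half of all
  draws are exactly Cr = 0 — trials then change a single coordinate and
  the adaptation cannot escape. We observed exactly this stall (archive
  statistics flat for hundreds of iterations) before switching.
* **Single-objective variant** for the baselines: greedy selection
  f(U) ≤ f(X), mutation base drawn from an elite set that admits every
  accepted trial and evicts its worst member beyond capacity.

## Objectives

* **Filter:** f₁ = |S|; f₂ = −mean I(s_i; c); f₃ = mean pairwise
  I(s_i; s_j) with self-pairs excluded and the divisor kept at |S|²
  (a singleton has f₃ = 0). Excluding self-pairs is forced by the
  estimator: I(s_i; s_i) is the differential-entropy limit and undefined
  under KNN estimation.
* **Wrapper:** f₁ = |S|; f₂ = mean over folds of the per-fold NB error
  (per-fold mean rather than pooled counts; the two differ when fold
  sizes differ). The inner 5-fold split is stratified and frozen per
  optimizer run, which removes evaluation noise and makes runs exactly
  reproducible; whether folds should be resampled per evaluation is
  unspecified in the underlying method, and freezing is the
  reproducible choice.
* **Baselines:** DE1 = ErrorRate; DE2 = α|S|/M + (1−α)·ErrorRate,
  α = 0.2 by default.

## Estimators and numerics

* Gene-gene MI: Kraskov-Stögbauer-Grassberger estimator, variant 1,
  Chebyshev metric, k = 3 neighbors (`knn_k`). Gene-class MI: the
  class-conditional neighbor-counting analogue (radius = distance to the
  k-th within-class neighbor; count of pool points strictly inside).
  Neighbor counts compare distances directly rather than shifted
  coordinates — adding a tiny radius to a coordinate of much larger
  magnitude rounds away and silently includes boundary points.
* All MI values are in nats and clipped below at 0, so redundancy sums
  stay nonnegative. Duplicate values break KNN distance ranking, so
  continuous inputs receive uniform jitter of amplitude 1e-10 × the
  sample sd, keyed deterministically on the array contents and the run
  seed; estimates are therefore reproducible and symmetric in their
  arguments.
* The relevance/redundancy cache computes all per-gene relevances
  eagerly and gene-pair redundancies lazily, in vectorized batches over
  the missing pairs of each queried subset. At microarray sample sizes
  (n ≤ ~100) the batch path broadcasts the n×n distance computation over
  chunks of pairs; filling all 124,750 pairs of a 500-gene problem takes
  a few seconds.
* Gaussian NB uses maximum-likelihood per-class means and variances with
  a variance floor of 1e-9 × the largest feature variance (constant
  features stay evaluable); exact posterior ties resolve to class 0.

## Pipeline and protocol

* Stage 1 runs MODE over all M genes. The handoff to stage 2 is the
  archive member with the smallest |S|, ties broken by smaller
  redundancy, then smaller (more negative) relevance, then insertion
  order. Stage 2 restricts the data to those columns and runs MODE in
  the reduced space; reported subsets are mapped back to original
  coordinates.
* Outer evaluation: stratified 5-fold; selection sees only the training
  split; a subset's test error comes from an NB classifier refit on the
  entire training split (not the inner folds) and applied to the held-out
  fold. Solutions pooled over folds form the union set; the "average"
  front is the mean test error per distinct subset size, the "best"
  front the nondominated (size, error) pairs, and training-front
  selection picks the solutions nondominated in (training error, size) —
  test values never influence selection. `Dataset` counts matrix reads,
  and the protocol asserts that held-out rows were never read during
  selection.
* Full-scale defaults (the published settings) are NP=100/N_a=200/
  Ite=10000 for the filter and NP=50/N_a=100/Ite=400 with λ=0.5 for the
  wrapper (`RunConfig.paper_profile()`); the package default profile is
  scaled (NP=30/N_a=60, Ite in the hundreds) for desk-scale runs. The
  filter λ has no published value ("tuned per dataset"); the default
  rule targets an expected initial subset of min(200, M/10) genes,
  λ = 1 − min(200, M/10)/M clamped to [0.5, 0.99], matching the
  magnitude of published filter-stage subset sizes without copying
  unreported per-dataset values.
* All randomness flows from one seed through `numpy` SeedSequence
  spawning, in a fixed order (outer folds, then per-fold filter /
  wrapper / de1 / de2 / inner folds), so any stage can be reproduced in
  isolation and repeat runs are bit-identical.

## Synthetic data

`SynthSpec`/`make_dataset` emulate the small-n / large-p microarray
regime: `n_informative` genes are class-conditionally N(∓δ/2, 1) (δ =
`effect`, in sd units), `n_redundant` genes are ρ·parent + √(1−ρ²)·ε
with parents cycled over the informative block, and `n_noise` genes are
independent N(0,1). Labels are Bernoulli(`class_balance`). Because the
informative genes are conditionally Gaussian and independent, the Bayes
error of an m-gene informative subset is Φ(−δ√m/2), which anchors what
the wrapper stage can attain. The generator does not model spot
artifacts, batch effects, correlated noise, or heavy tails — passing
recovery tests here shows the machinery works on clean planted
structure, not that it handles real microarray pathology.

The benchmark used by the test suite and `scripts/acceptance.py` is
60 samples × 500 genes (5 informative at δ=2, 20 redundant at ρ=0.9,
475 noise), run at a scaled profile (filter NP=20/Ite=200, wrapper
NP=20/Ite=100) over 10 seeds, with selection on the 60 samples and test
errors measured on a fresh 400-sample draw from the same process —
exact generalization errors that selection never sees.

## Known limitations

* **Filter-front geometry.** Because a subset's mean relevance can never
  exceed its best single gene and a singleton has zero redundancy, the
  exact Pareto front of the filter objectives collapses toward the
  single gene with maximal estimated relevance; with enough iterations
  the smallest archive member is a singleton. At n = 60 the estimated
  top gene is frequently a ρ=0.9 redundant copy rather than its parent
  (their true effects differ by only 10%), so converged smallest subsets
  recover a planted *signal* gene essentially always, but the specific
  parent only about half the time. Published full-scale runs stop far
  from this collapse (filter subsets of hundreds of genes), where the
  smallest-subset handoff is signal-rich; at desk scale the handoff can
  be a single gene and the wrapper then has little to refine.
* **All-features reference.** On the clean Gaussian generator the
  all-features NB classifier is close to Bayes-optimal (test error
  0.02–0.06 at p/n ≈ 8), so selection cannot beat it there; the
  practical advantage of selection over no-selection comes from
  real-data pathologies the generator deliberately omits.
* Binary classes only; no normalization or batch correction; no
  imputation (missing values are rejected); no multi-class MI.
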