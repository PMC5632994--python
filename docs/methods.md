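# Methods

## Problem setting

`twophase` addresses classifiers trained on stratified samples from
two-phase case-control designs. Such a design enriches both a rare binary
outcome `Y` (cases) and a rare categorical exposure `X_e`, so the learning
sample follows a different distribution than the population the fitted
model will score (complete sample selection bias: selection depends on both
the features and the label). The strata are the `(X_e, Y)` cells; all
members of a cell share the selection probability `P(S=1|h) = n_h / N_h`.

All corrections are driven by the integer inverse-probability weight

    w_h = [ max_h' P(S=1|h') / P(S=1|h) ],

rounded to the closest integer (we round half away from zero, so a ratio of
exactly 1.5 becomes 2, and ratios are floored at 1). Using the rounded
ratio rather than `1/P(S=1|h)` keeps the reconstructed sample as small as
possible: its total size is `n' = Σ_h n_h·w_h`. The unrounded ratios are
retained in the stratum table (`raw_ratio`) for diagnostics, since the
rounding error can be material when a ratio sits near `x.5`. Selection
probabilities are assumed known (they are, by design, in a two-phase
study); estimating them is out of scope.

## The seven corrections

* **none** — train on the biased sample as-is.
* **IP oversampling** — replicate each row of stratum `h` exactly `w_h`
  times (deterministic, size `n'`). For likelihood-based classifiers this
  equals frequency-weighting the log-likelihood with integer weights, a
  property enforced by an exact-agreement test. Replication shrinks the
  expected within-stratum empirical covariance to `w(n-1)/(wn-1)·Σ`.
* **IP bagging** — `m` bootstrap samples of size `n` with per-row selection
  probability proportional to `w_h`.
* **costing** — `m` rejection subsamples: each row enters at most once,
  accepted with probability `w_h / max w`. Subsamples missing a nonempty
  stratum are discarded and redrawn (cap 1000 per subsample, rejection
  counts logged); the induced conditioning bias is treated as negligible.
* **modified SMOTE** — for each stratum with `w_h > 1`, every member
  generates `w_h − 1` synthetic rows `x + u·(x_nn − x)` with
  `u ~ Uniform(0,1)` and `x_nn` one of its `k` Euclidean nearest neighbours
  *within the same stratum* (k defaults to the classic 5; distances on raw
  feature scales; ties broken by row order). Output size is `n'`. The
  target count per stratum, `n_h(w_h − 1)` new rows, is chosen so every
  corrected sample reaches exactly `n_h·w_h` rows per stratum.
* **stochastic IP oversampling** — IP oversampling plus mean-zero Gaussian
  noise on the main features, per stratum, with covariance

      Σ_adj = (w_h − 1) / (w_h·n_h − 1) · Σ̂_h,

  which makes the expected empirical covariance of the enlarged stratum
  equal `Σ̂_h`. The noise is added to **all** `n_h·w_h` replicated rows,
  originals included: only then does the restoration identity hold exactly,
  which a Monte-Carlo property test verifies directly (p=2, n_h=50,
  w ∈ {2,3,9}, 10⁴ repetitions, 3 MC standard errors). `w_h = 1` strata
  receive exactly zero noise, so the all-weights-one limit is the identity.
* **parametric IP bagging** — `m` parametric bootstrap samples of size
  `n'`: per stratum, fit `μ̂_h, Σ̂_h` (empirical mean/covariance) and draw
  `n_h·w_h` feature vectors from `N(μ̂_h, Σ̂_h)`, attaching the stratum's
  `(x_e, y)`. The family is pluggable in the interface but currently
  multivariate normal only.

Numerical choices: singular `Σ̂_h` gets a ridge `λI` with
`λ = 1e-8·mean(diag Σ̂_h)` (or `1e-8` when that is zero) before the
Cholesky factorization — enough to sample, too small to matter. The
noise-based corrections deliberately treat every main feature as
continuous Gaussian even when it is not (that robustness question is
exactly what the simulation scenarios probe); noisy values are not rounded
or clipped.

Randomness: each ensemble repetition `j` uses the `j`-th spawned child of
`numpy.random.SeedSequence(seed)`, so increasing `m` never perturbs
earlier repetitions and all outputs are reproducible bit-for-bit.

## Classifiers

Logistic regression (unpenalized MLE; perfect separation is flagged via
the iteration cap or exploding coefficients, and the terminal iterate is
still used for scoring), logistic regression with all two-way interaction
products among {stratum feature, main features}, naive Bayes with
univariate Gaussian-KDE class-conditionals (Silverman bandwidth
`0.9·min(sd, IQR/1.34)·n^{-1/5}`, floored at `1e-6·(range+1)`; the
categorical stratum feature contributes plain class-conditional
frequencies floored at 1e-12), and a random forest. The stratum feature is
always a predictor; features are never standardized (the MLE is
equivariant, KDE and trees work on raw scales).

The single-sample corrections (none, IP oversampling, SMOTE) fit one
model; the resampling corrections fit `m` models (default 100 outside the
forest) and average risk scores. For the forest, bagging is not nested
inside bagging: each of the `n_trees` (default 500) fully grown CART trees
(mtry = floor(sqrt(#predictors)), minimum leaf size 1) is grown on one
freshly drawn corrected sample. Under "none" that is the ordinary
bootstrap of size `n`; under IP oversampling it is an IP-weighted
bootstrap of size `n'` (inside a forest the two IP methods coincide up to
sample size); under SMOTE the synthetic set is built once and each tree
bootstraps it. Trees average predicted class-1 leaf frequencies
(probability forest), consistent with rank-based AUC evaluation. A tree
whose corrected draw contains one outcome class is refit on a redrawn
sample (cap 100); the same redraw rule protects ensemble members of the
bootstrap-based corrections, whose draws can miss a class at extreme
weights.

## Synthetic study

Each replicate draws feature-distribution parameters afresh
(`μ ∈ [1,10]`, `σ ∈ [1,5]`, `ν ∈ {10..100}`, `λ ∈ {1..5}`,
`π ∈ [0.4,0.6]`) and slopes `β_j ~ U[-0.15, 0.15]`; the exposure effect is
fixed at `β_e = log 0.5` and the intercept `β_0` is found by bisection on
`b ↦ mean(expit(b + linear predictor)) − 0.1` over `[-50, 50]` to 1e-10.
The test set is generated with the same replicate parameters (including
the population-calibrated intercept). The learning sample takes `n/4` rows
without replacement from each `(x_e, y)` cell, so sample case and exposure
fractions are exactly 0.5 while the population rates are 0.1. Population
cell counts give the exact selection probabilities of the design; the
rarest cell always receives weight 1. The defaults mirror the reference
conditions: `N = 1e5`, `n_test = 1e4`, 1000 replicates. The learning-set
size is not pinned down by the scenario description, so it defaults to
`n = 2000` — the size used in the companion real-data design — and is
configurable.

Evaluation: AUC via the Mann–Whitney midrank formulation (ties count
half), a DeLong paired test for correlated AUCs (zero variance returns
statistic 0 and p = 1), a Bonferroni helper (`α/n_tests`, e.g. 0.05/7 ≈
0.0071 for the seven pairwise comparisons), and an OLS of AUC on
correction dummies with "no correction" as reference, whose coefficients
are exactly group-mean AUC differences and whose 95% t-intervals define
significance.

### Scaled-down study in the test suite

The packaged acceptance test replays the qualitative findings at a reduced
scale chosen to keep a full run on one CPU within minutes: populations of
10,000 (test sets of 2,000), learning samples of 100 (four strata of 25),
50 replicates, 100-tree forests and `m = 20` ensemble fits. This preserves
the design's weight structure (the common-to-rare cell ratio, hence
weights near (150, 18, 18, 1) and `n' ≈ 4,700`) while shrinking
everything else proportionally. Checks are directional (mean-AUC
orderings), not significance-based, because 50 replicates at this sample
size cannot resolve the small effects the full-scale study reports.

A caveat that the suite itself makes visible: the benefit of weighting
corrections depends on the learning-sample size. A two-phase sample is
outcome-balanced by construction, which is itself an advantage for fitting
on very small samples; with only 25 rows per stratum the extra variance a
correction introduces can offset the bias it removes, and some of the
directional orderings that hold at the full-scale conditions (n = 2000)
need not hold at n = 100. The relative ordering *among* corrections — the
parametric IP bagging ahead of the replication-based ones for the forest —
is more stable across scales than each correction's comparison against no
correction.

## What the generator does and does not emulate

It emulates: rare outcome and exposure, independent main features from
four families, a correctly specified logistic outcome model, exact
two-phase stratification with known selection probabilities. Optional
knobs support correlated features (Gaussian copula) and per-feature family
mixes, without headline claims. It does not emulate: unknown or estimated
selection probabilities, model misspecification of the outcome,
measurement error, missing data, or continuous stratum features (rejected
by design). Passing tests therefore demonstrate correct behaviour of the
corrections under the stated design, not robustness to those
complications.

## Known limitations

* Parametric corrections assume roughly Gaussian main features; with
  strongly discrete features (Bernoulli) the assumption is knowingly
  violated — the study scenarios quantify the consequences rather than
  hide them.
* Categorical *main* features have no dedicated parametric treatment
  (subgrouping by category is a possible extension, not implemented).
* Costing's completeness filter conditions on all strata being present,
  a small bias accepted by construction; rejection rates are recorded.
* `w_h` rounding can be coarse when selection-probability ratios are
  small and non-integer; inspect `raw_ratio` in the stratum table.
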