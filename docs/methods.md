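# Methods

## The pipeline and its assumptions

`radeq` treats a radiomic analysis as a fixed, fully enumerated model grid
rather than a single chosen pipeline. For one dataset the procedure is:

1. **Preprocessing.** Missing cells are imputed with the column's observed
   mean, then every column is z-scored (sample sd, divisor n−1). Both steps
   are fitted on the whole dataset before cross-validation — the common
   radiomic workflow this framework is built to study, which mildly leaks
   test-fold scale information. `Preprocessor.fit/transform` provides the
   leakage-free fold-wise alternative for users who want it; the study runner
   deliberately uses the global variant. Zero-variance columns are dropped
   (several scorers are undefined on constants). Mean imputation is only
   defensible under MCAR missingness, which is also what the generator
   produces.
2. **Model grid.** 8 feature-scoring methods × N ∈ {1, 2, 4, 8, 16, 32, 64}
   × 65 classifier hyperparameter points (see `harness.classifier_grid`),
   3640 configurations. Hyperparameter grids are fixed; there is no nested
   tuning, no external validation split.
3. **Cross-validation.** One stratified 10-fold split per dataset, shared by
   *all* configurations. Sharing is essential, not cosmetic: the paired
   DeLong test couples two models through their per-sample out-of-fold
   scores, which is only meaningful when both models scored each sample
   under the same partition. Per fold, features are scored and the top N
   selected on the nine training folds only; the classifier is fitted on the
   selected columns and emits a continuous score for the held-out fold
   (event-class probability where available, otherwise the decision value —
   AUC is rank-based, so any monotone score is equivalent).
4. **Evaluation.** Out-of-fold scores are pooled into one Mann–Whitney AUC
   per configuration (ties ½). The best configuration per
   (scorer, classifier) pair — ties broken by enumeration order — gives 64
   models; each is compared to the overall best with the paired DeLong test.
   Models with p ≥ α (default 0.05, no multiplicity adjustment — adjusting
   would only enlarge the set) form the equivalence set.
5. **Agreement.** Stability, similarity and feature-set correlation are
   computed from the per-fold binary selection indicators (definitions in
   the README); the study summary reports mean and (min, max) range of each
   over the equivalence set, plus OLS regressions of the per-dataset mean
   equivalence-set AUC against the equivalent-model count and the three
   agreement means (two-sided t-test on the slope).

## Scoring methods: estimators and conventions

- **anova** — one-way F between outcome groups (scikit-learn `f_classif`).
- **bhattacharyya** — closed-form distance between class-conditional
  univariate Gaussians, D = (μ₁−μ₀)²/(8σ̄²) + ½ln(σ̄²/(σ₀σ₁)); class
  variances are floored at 1e−12 with a warning.
- **kendall** — |τ-b| against the outcome (scipy). With a binary outcome the
  tie correction caps |τ-b| below 1 even at perfect separation.
- **mim / fcbf** — information-theoretic scores use equal-frequency binning
  of continuous features into ⌈√n⌉ bins and plug-in entropies in nats. This
  is a deliberate, stated estimator choice: reproducible and cheap, at the
  cost of the usual plug-in bias (small positive MI for independent pairs).
  FCBF keeps every feature in the ranking (relevance threshold 0) and applies
  the classic predominant-correlate elimination; eliminated features score
  SU − 2, strictly below any survivor, so top-N selection always succeeds.
- **lasso** — |coefficients| of an L1 logistic model at fixed C = 1.0
  (liblinear). All-zero coefficient vectors are valid; selection then falls
  back to the index tie-break.
- **extratrees** — impurity importances of a 100-tree extremely-randomized
  ensemble, seeded.
- **mrmre** — greedy mRMR (relevance |r(x, outcome)| minus mean |r| with the
  already-selected set), run on 5 bootstrap resamples of the rows; each
  member selects up to 64 features (the largest N ever requested); a
  feature's score is its mean inverse selection rank, unselected = 0. The
  ensemble aggregation is our own convention — inverse rank is monotone in
  selection order and stable across members.

Ties break by ascending feature index everywhere (stable argsort), making
selections — and therefore the stability statistics — bit-reproducible.

## The DeLong implementation

Placements are computed with midranks (three `rankdata` calls), so tied
scores — ubiquitous in pooled CV output from tree ensembles — are handled
exactly as in the reference formulation; the placement mean reproduces the
pair-counting AUC to 1e−12 (asserted). Covariances use ddof = 1; the z
statistic is referred to a standard normal (the construction is
asymptotically normal; no t correction).

Degenerate cases: identical predictions → p = 1 by construction. A zero
variance of the AUC *difference* with unequal AUCs indicates a pathological
fixture (e.g. two anti-perfect models) and raises `DegenerateVarianceError`
rather than fabricating p = 0. The one-sample comparison against the
constant model (AUC exactly 0.5, zero-variance placements) distinguishes the
two zero-variance regimes: all-tied scores (AUC 0.5) give p = 1, perfect
separation (every placement exactly 0 or 1) gives p = 0 — there the variance
estimate collapses at the boundary while the evidence is maximal.

Calibration is checked by simulation: under two exchangeable null models
(independent N(0,1) scores, m = n = 100), the empirical type-I error at
α = 0.05 over 2000 replicates is asserted to lie in the 95% binomial
envelope, and the implementation is cross-checked against an O(n²)
pair-counting covariance oracle and against a frozen reference p-value from
an independent implementation of the same closed form.

## Agreement-measure conventions

Pearson correlation of indicator vectors is undefined when a vector is
constant (empty selection, or select-all after capping N at d). An identical
pair of vectors scores exactly 1.0 — constants included — preserving the
boundary semantics "same sets in every fold ⇒ 1.0"; a non-identical pair
involving a constant scores 0 with a logged warning.

Stability averages over the 45 unordered fold pairs; similarity averages
over the 10 matched folds (both models saw the same training data per fold).
Under these conventions self-similarity on matched folds is trivially 1, so
`similarity(..., pairing="cross")` averages over ordered distinct fold pairs
instead, and with A = B reproduces stability exactly (asserted). The
feature-set correlation uses *absolute* Pearson r — anti-correlated features
carry the same information — and computes correlations on the full
preprocessed table, not per-fold training data, since it characterizes the
dataset's redundancy structure. The all-pairs correlation histogram defaults
to 100 equal-width bins on [−1, 1], subsampling pairs (seeded, with a
warning) beyond 2×10⁶ pairs.

## The synthetic generator

`generate_radiomic_dataset` emulates the statistical signature of public
radiomic tables: n ≪ d, blocks of highly inter-correlated features, a small
informative minority, class imbalance, occasional missing values. Defaults
(n = 300, d = 500, 8 informative features at standardized shift δ = 1.5,
eight 25-feature blocks at ρ = 0.8, 30% events, 1% missing cells) describe a
typical mid-sized cohort.

Mechanisms, chosen for testability:

- **Blocks** via one shared latent factor: x = √ρ·z + √(1−ρ)·ε gives exact
  equicorrelation at ρ with unit marginal variance.
- **Signal** is an additive mean shift δ on the event class, applied to
  informative features placed in distinct blocks first; a single informative
  feature then has closed-form AUC Φ(δ/√2), the analytic oracle used by the
  end-to-end CV tests.
- **Outcome counts** are deterministic (⌈n·event_rate⌉ events, shuffled,
  clamped so both classes exist), guaranteeing stratified CV is possible.
- **Missingness** is MCAR over cells, with at least one observed value kept
  per column so mean imputation is always defined.

What it does *not* emulate: non-Gaussian marginals, feature-scale
heterogeneity, cross-block correlation, informative missingness, batch or
scanner effects, and any specific real dataset's joint distribution. Passing
tests on this generator therefore validate the machinery and its calibrated
null behavior, not claims about any particular real cohort.

Scenario notes: the "stability rises with N" pattern is exercised on
signal-free tables. Fold rankings correlate through their 8/9-overlapping
training data, and larger top-N cuts are more robust to rank jitter than the
top few positions; a strong sparse signal would instead pin the small-N
selections and flatten or invert the low-N end — consistent with the
observation that real radiomic data behave as if no small dominant feature
set exists. The equivalence-count-versus-AUC scenario spans effect sizes
0.1–1.0 at n = 200 so best AUCs cover weak-to-strong without saturating at
1.0, where all models tie and the count rebounds.

## Reproducibility and problem sizes

One master seed drives everything: child seeds derive from
(master, label...) via a splitmix64 finalizer (recorded in run manifests),
for the CV split, each stochastic scorer per (method, fold), and each
stochastic classifier per (config, fold). Scorer seeds deliberately do not
depend on the classifier or N: feature relevance is a property of the
scoring method and the training data, which also lets the study runner reuse
one score vector across a classifier grid. Reruns with the same
configuration are byte-identical (asserted on the persisted JSON).

The test suite and the acceptance script run at desk scale by choice:
reduced grid axes (2–3 scorers, 2–3 classifiers, 3 feature counts),
synthetic cohorts of n = 60–400 and d = 30–500, 2000 replicates for test
calibration, 5 seeds for recovery checks. The full 3640-configuration grid
is exercised structurally (enumeration, best-per-pair bookkeeping) rather
than trained end to end.

## Known limitations

- Global z-scoring before CV reproduces the workflow under study, including
  its mild leakage; switch to `Preprocessor` for honest generalization
  estimates.
- The equivalence set is defined by non-rejection at α = 0.05, which is not
  formal equivalence testing (no TOST); low power inflates the set — a
  property of the analyzed workflow itself.
- Plug-in MI with √n binning is biased upward for independent pairs; it is
  used for ranking only.
- The mRMRe aggregation and the FCBF full-ranking extension are stated
  conventions, not canonical definitions; both are tested against their
  stated contracts.
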