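# Methods

## Problem setting

The package targets binary diagnosis from tabular clinical risk factors in
the layout of the public cervical-cancer screening dataset: 858 patients,
32 factors (demographics, smoking and contraceptive history, STD
indicators, prior diagnoses), and four binary screening/diagnostic
outcomes — Hinselmann, Schiller, Cytology and Biopsy — each treated as an
independent classification problem. All four outcomes are rare (4.5–9.4%
positive), and many cells are missing because patients declined to answer.

## Preprocessing

Two factors (ids 27 and 28, "time since first/last STD diagnosis") are
dropped by default because they are almost entirely missing. The row
filter then removes every row with a missing value in any retained factor
or target column. The source protocol says only that "some samples were
removed"; complete-case filtering after the column drops is the rule that
reproduces the published 668-row count, and the preprocessing report
carries a warning when observed target prevalences deviate from the
published 4.5/9.4/5.8/6.7% by more than half a percentage point.

Continuous factors are min–max scaled to [0, 1] (constant columns map to
0); binary 0/1 indicator factors pass through. Min–max was chosen over
standardization because bounded inputs suit logistic/tanh MLP hidden
units, and which columns were scaled in the source work is not recorded.
A column is treated as binary exactly when its observed values lie in
{0, 1}.

Class balance is restored by random oversampling: minority rows are
duplicated uniformly at random with replacement until the class counts
are equal. Majority rows are never touched, the balance is exact, and the
result is deterministic given the seed. SMOTE-style interpolation and
cost-sensitive weighting are deliberately out of scope.

## Feature-selection modes

Four modes feed the evaluation grid:

* `pca2` — projection onto the two leading principal components of the
  column-centered covariance matrix. Eigen-signs follow the convention
  that each component's largest-magnitude loading is positive, so fits
  are platform-reproducible. No varimax/oblique rotation is applied:
  rotation would not change any scenario definition and no rotated
  loadings exist to compare against.
* `all30` — identity (all retained factors).
* `top18` / `top10` — the k factors with the highest random-forest Gini
  importance, in ranking order. Rankings can be recomputed (500 trees by
  default, seeded, ties broken by the smaller factor number) or taken
  from the packaged reference tables, which list the published top-18
  orderings per target; the top-10 list is the prefix of the top-18 list
  for every target. The packaged tables are the default for reproducing
  scenario definitions because recomputed forests on different data
  cannot reproduce them.

## The GA–MLP hybrid

Each candidate solution is a chromosome of four real genes in [0, 1)
decoding by scaled floor to: activation (identity, logistic, tanh, ReLU),
solver (L-BFGS, SGD with momentum, Adam), and two hidden-layer sizes in
1..50 — a 4 × 3 × 50 × 50 space of 30,000 networks. Fixed training
parameters for every network: learning rate 0.001, momentum 0.90 (only
meaningful for SGD; the other solvers have no classical-momentum term),
at most 200 iterations.

The GA is generational and non-elitist. Defaults: population 50,
200 generations, tournament selection with k = 4 (contestants sampled
without replacement, ties to the lowest population index), single-point
crossover with probability 1 at a cut point uniform in {1, 2, 3},
per-gene mutation with probability 0.001 that resamples the gene uniform
on [0, 1). Children fully replace parents; a separate archive retains the
best solution over all generations, which makes the recorded
best-per-generation sequence non-decreasing even though the population
itself can regress. The per-generation history stores the archived best
(not the population best) together with the population mean fitness.
Fitness values are cached per decoded genotype, so hyperparameter
combinations revisited by the search never retrain.

Fitness is the stratified 5-fold cross-validated accuracy (as a
percentage) of the decoded network on the balanced, feature-selected
data; a `holdout:F` mode scores a single stratified holdout instead for
large search budgets. Which accuracy the source protocol used as fitness
is not recorded; CV matches its reported evaluation metric.

Design points that were genuinely open and how they were resolved:
mutation granularity is per gene (the source fixes only the
probability); the scaled-floor decoding keeps the variation operators
closed over valid genotypes; tournament tie-breaking and
without-replacement sampling were chosen for determinism. One known
consequence of uniform-resample mutation is weak local refinement: at
mutation probability 0.01 a 20 × 30-generation run resamples the
layer-size gene only ~6 times, so extreme decoded values (e.g. a
hidden-layer size of exactly 50) are found in roughly 40% of runs, not
reliably — the acceptance suite documents this honestly rather than
inflating the mutation rate.

## Evaluation

The metrics suite computes accuracy, sensitivity, specificity, precision
and F1 from TN/FP/FN/TP counts (positive = disease present), all as
percentages; a zero denominator yields 0 with the metric flagged
undefined. F1 is the harmonic mean of sensitivity and precision.

Cross-validation is stratified 5-fold by default, with two leakage
placements because the source pipeline balances the data *before*
describing cross-validation and never clarifies the ordering:

* `fold_safe` (default): oversampling, PCA fitting and importance
  ranking are fitted on the training folds only and applied to untouched
  test folds. Test folds keep the source prevalence.
* `paper_global`: balancing and feature fitting happen once on the full
  dataset before splitting, so oversampled duplicates can straddle fold
  boundaries. This mode exists to measure the optimistic bias; on
  duplicate-heavy data a memorizing learner scores higher under it, a
  directional property the test suite checks across seeds.

Fold metrics aggregate as the macro mean of per-fold percentages by
default; pooled-counts aggregation (metrics of the summed confusion
matrix) is available.

The grid crosses 4 targets × 4 feature modes (16 scenarios) × 10 methods
(160 experiments). Nine baselines use scikit-learn estimators at library
defaults with fixed seeds, recorded in each run's manifest. CD-KNN — a
centroid-displacement k-nearest-neighbour baseline whose original
description is not available in the source material — is implemented as
an interpretation: among a query's k nearest training neighbours, the
predicted class is the one whose neighbour-centroid the query is closest
to. For GA-MLP cells, the hyperparameter search runs on the balanced,
feature-selected full dataset (mirroring the balance-then-search
ordering of the source framework) and the best decoded network is then
re-evaluated under the requested CV protocol.

## Synthetic data

The generator emulates the screening schema, not the screening data: ~30
mixed factors (right-skewed lognormal age-like and gamma years-like
continuous columns, Bernoulli indicators), four low-prevalence targets at
the published 4.5/9.4/5.8/6.7% rates by default, and a logistic planted
signal linking chosen factors to each label (defaults: age,
first-intercourse age and contraceptive-years, echoing the top of the
published importance rankings). Labels are drawn from the logistic model
and then adjusted by label swaps — removing positives with the lowest
model probability first — so the positive count equals
round(n × prevalence) exactly, which makes prevalence assertions
deterministic. Missing cells are injected at a configurable rate (default
0: the real missingness mechanism is informative non-response, which the
generator does not model). Marginal shapes are schema-inspired; no
attempt is made to match the real data's marginals or correlations, so
green pipeline tests demonstrate mechanical correctness and sane
statistical behaviour, not clinical performance.

`make_separable` builds two balanced clouds a set distance apart along a
random direction for classifier oracles. The noise component along that
direction is a standard normal truncated at ±2.5, so any margin above 5
leaves a guaranteed inter-class gap (linear separability is certain, not
merely likely), while margin 0 gives pure overlap and chance-level
accuracy.

## Problem sizes and numerical choices

The packaged end-to-end checks run at reduced sizes chosen to keep the
pipeline's behaviour measurable on a single CPU: GA-MLP on separable data
uses population 10 × 10 generations on 400 rows (accuracy ≥ 95% expected);
the null-data sanity check uses a 50/50-prevalence zero-effect dataset of
400 rows with a population 6 × 3-generation search and holdout fitness,
expecting chance-level (40–60%) final CV accuracy — a balanced null is
used because under fold-safe CV a rare-outcome null would pin accuracy
at the majority rate regardless of the classifier, telling us nothing.
Planted-factor recovery plants three strong effects (2.0 per SD on the
log-odds) among 30 factors at 400 rows.

Degenerate inputs: constant columns scale to 0; rank-deficient PCA pads
zero-variance components with a warning; single-class targets, empty
tables and malformed rows raise immediately with the offending row or
column named. Determinism: every stochastic component takes an explicit
seed; the CLI fans a single global seed out through a fixed hash
derivation so subsystems remain independently reproducible, and every
command writes a manifest sufficient to reproduce the run.

## Known limitations

* The published headline accuracies (e.g. 98.20% for Hinselmann under
  PCA) depend on the external dataset and on a likely leakage-prone
  balance-before-split protocol; they are reproducible as an experiment
  (`--leakage-mode paper_global` on the real CSV) but are not asserted
  anywhere, and fold-safe results on rare outcomes will be substantially
  lower — that gap is the point of shipping both modes.
* CD-KNN is an interpretation, not a reimplementation, of its cited
  method.
* The synthetic generator's missingness is completely at random, unlike
  the real non-response mechanism.
* The GA's uniform-resample mutation explores but does not locally
  refine; see the GA section.
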