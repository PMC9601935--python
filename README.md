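# gamlp

Genetic-algorithm-optimized multilayer perceptrons for cervical-cancer
risk-factor screening tables.

Cervical-cancer screening datasets pair ~30 clinical risk factors
(demographics, smoking and contraceptive history, STD indicators, prior
diagnoses) with four rare binary outcomes — the Hinselmann, Schiller,
Cytology and Biopsy tests, each 4.5–9.4% positive. This package
implements, as a tested library and CLI, an integrated
PCA–GA–MLP diagnosis framework for such tables, aimed at
anyone who wants to study hyperparameter-evolved neural classifiers on
imbalanced tabular clinical data without hand-rolling the surrounding
pipeline.

## The method

A candidate MLP is encoded as a chromosome of four genes
g ∈ [0, 1)⁴ decoding to

    activation = ⌊4·g₁⌋ ∈ {identity, logistic, tanh, ReLU}
    solver     = ⌊3·g₂⌋ ∈ {L-BFGS, SGD+momentum, Adam}
    h₁, h₂     = ⌊50·g₃⌋+1, ⌊50·g₄⌋+1   (hidden-layer sizes, 1..50)

with fixed training parameters (learning rate 0.001, momentum 0.90,
≤ 200 iterations). A generational GA (population n = 50, gmax = 200
generations, tournament selection k = 4, single-point crossover
Pc = 1, per-gene mutation Pm = 0.001, non-elitist replacement with a
best-over-run archive) maximizes the fitness

    f(g) = stratified 5-fold CV accuracy of the decoded MLP, in %

Around the search sits the full pipeline: `?`-aware CSV ingestion,
factor drops + complete-case filtering + min–max scaling, random
oversampling to exact class balance, four feature-selection modes
(2-component PCA, all factors, random-forest Gini-importance top-18 /
top-10 — recomputed or from the packaged reference rankings), the five
confusion-matrix metrics (accuracy, sensitivity, specificity,
precision, F1, as percentages), and a 4 targets × 4 modes × 10 methods
grid (16 scenarios, 160 experiments) with nine scikit-learn baselines
plus a centroid-displacement KNN. Cross-validation offers two leakage
placements — `fold_safe` (balance/fit inside training folds; the
default) and `paper_global` (balance/fit before splitting) — so the
optimistic bias of balancing before the split can be measured rather
than silently inherited. See `docs/methods.md` for the full model
description and design rationale.

## Worked example

Everything below runs on synthetic data emulating the screening schema
(no downloads). Generate a 400-patient cohort, preprocess it, evolve an
MLP for the Schiller test on the two leading principal components, and
evaluate a random-forest baseline on the top-10 factors:

```
$ gamlp synth cohort.csv --n-rows 400 --n-factors 32 --seed 7
wrote 400 rows x 32 factors -> cohort.csv

$ gamlp preprocess cohort.csv prep
retained 400/400 rows, 30 factors -> prep/clean.csv

$ gamlp optimize cohort.csv opt --target Schiller --mode pca2 \
      --population 10 --generations 10 --seed 7
best: tanh/lbfgs (42,32) fitness=91.58 cv_accuracy=80.50

$ gamlp evaluate cohort.csv eval --target Schiller --mode top10 \
      --method RF --seed 7
{"accuracy": 93.25, "sensitivity": 33.93, "specificity": 99.44,
 "precision": 95.0, "f1": 44.44}
```

Reading the numbers: `fitness=91.58` is the best genotype's CV accuracy
on the *balanced* data the GA searches, while `cv_accuracy=80.50` is the
same network re-evaluated under the default fold-safe protocol, where
test folds keep the cohort's real ~9% prevalence — the gap is the
leakage/balance effect the two CV modes exist to expose. The RF baseline
shows the classic imbalanced-data signature: high accuracy and
specificity, low sensitivity. `gamlp grid cohort.csv out --dry-run`
lists all 160 experiment fingerprints; dropping `--dry-run` runs them
and writes a `method × metrics` results table per run manifest.

Every command writes a `manifest.json` with the full configuration and
derived seeds, and identical seeds reproduce results bit for bit.

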