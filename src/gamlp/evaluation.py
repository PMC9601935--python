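"""Metrics, the cross-validation harness, and the scenario/experiment grid.

The grid crosses four screening-test targets with four feature-selection
modes (16 scenarios) and ten classification methods (160 experiments). The
cross-validation harness supports two leakage placements:

``fold_safe``
    Oversampling and feature fitting (PCA / importance ranking) happen on
    the training folds only and are applied to the untouched test fold —
    the statistically sound protocol. Test folds retain the source class
    balance.

``paper_global``
    The dataset is balanced and feature-fitted once, before splitting, so
    oversampled duplicates can land on both sides of a fold boundary. This
    mirrors pipelines that balance the full dataset as a preprocessing
    step and is provided so the optimistic bias can be measured directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from gamlp.data_io import CleanDataset, oversample
from gamlp.features import (
    FeatureSelectionSpec,
    ImportanceRanking,
    PCAModel,
    fit_pca,
    get_fixture_ranking,
    rank_importance,
    select_features,
)
from gamlp.ga import GAConfig, MLPGenotype, run_ga
from gamlp.mlp import MLPTrainConfig, build_classifier, fitness_of

TARGETS = ("Hinselmann", "Schiller", "Cytology", "Biopsy")
FEATURE_MODES = ("pca2", "all30", "top18", "top10")
METHODS = ("GA-MLP", "RF", "LDA", "SVM", "LR", "GaussianNB", "KNN", "DT",
           "AdaBoost", "CD-KNN")


@dataclass
class ConfusionCounts:
    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tn + other.tn, self.fp + other.fp,
                               self.fn + other.fn, self.tp + other.tp)


@dataclass
class MetricsReport:
    """The five confusion-matrix metrics, as percentages in [0, 100].

    ``undefined`` lists metrics whose denominator was zero; by convention
    those report 0 rather than NaN.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "precision": self.precision,
                "f1": self.f1, "undefined": list(self.undefined)}


@dataclass
class CVConfig:
    k: int = 5
    stratified: bool = True
    seed: int = 0
    aggregation: str = "macro-mean"   # "macro-mean" | "pooled-counts"
    leakage_mode: str = "fold_safe"   # "fold_safe" | "paper_global"

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.aggregation not in ("macro-mean", "pooled-counts"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.leakage_mode not in ("fold_safe", "paper_global"):
            raise ValueError(f"unknown leakage mode {self.leakage_mode!r}")


@dataclass
class ScenarioSpec:
    target: str
    feature_mode: FeatureSelectionSpec
    method: str

    def __post_init__(self):
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def scenario_key(self) -> tuple[str, str]:
        return (self.target, self.feature_mode.mode)

    def fingerprint(self) -> str:
        return (f"{self.target}/{self.feature_mode.mode}"
                f"[{self.feature_mode.ranking_source}]/{self.method}")


class CentroidDisplacementKNN(BaseEstimator, ClassifierMixin):
    """k-NN variant that votes by minimal class-centroid displacement.

    For a query point, the k nearest training neighbours are found; for
    each class present among them the centroid of that class's neighbours
    is computed, and the query is assigned to the class whose local
    centroid it displaces least (i.e., the nearest neighbour-class
    centroid). Falls back to the plain majority class of the neighbours
    when a tie in displacement occurs.
    """

    def __init__(self, n_neighbors: int = 5):
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y, dtype=int)
        self.classes_ = np.unique(self.y_)
        self.nn_ = KNeighborsClassifier(n_neighbors=self.n_neighbors)
        self.nn_.fit(self.X_, self.y_)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        _, idx = self.nn_.kneighbors(X)
        out = np.empty(X.shape[0], dtype=int)
        for i, neigh in enumerate(idx):
            labels = self.y_[neigh]
            best_cls, best_disp = None, np.inf
            for c in np.unique(labels):
                centroid = self.X_[neigh][labels == c].mean(axis=0)
                disp = float(np.linalg.norm(X[i] - centroid))
                if disp < best_disp:
                    best_cls, best_disp = int(c), disp
            out[i] = best_cls
        return out


def baseline_estimator(method: str, seed: int = 0):
    """Unfitted classifier for a registry method (library defaults, seeded)."""
    registry = {
        "RF": lambda: RandomForestClassifier(random_state=seed),
        "LDA": lambda: LinearDiscriminantAnalysis(),
        "SVM": lambda: SVC(random_state=seed),
        "LR": lambda: LogisticRegression(max_iter=1000, random_state=seed),
        "GaussianNB": lambda: GaussianNB(),
        "KNN": lambda: KNeighborsClassifier(),
        "DT": lambda: DecisionTreeClassifier(random_state=seed),
        "AdaBoost": lambda: AdaBoostClassifier(random_state=seed),
        "CD-KNN": lambda: CentroidDisplacementKNN(),
    }
    if method not in registry:
        raise ValueError(f"no baseline estimator for method {method!r}")
    return registry[method]()


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """TN/FP/FN/TP with positive = disease present (label 1)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    bad = np.setdiff1d(np.union1d(y_true, y_pred), [0, 1])
    if bad.size:
        raise ValueError(f"labels must be 0/1, found {bad.tolist()}")
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    return ConfusionCounts(tn=int(tn), fp=int(fp), fn=int(fn), tp=int(tp))


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision and F1 from counts.

    accuracy   = (TP + TN) / (TP + FP + TN + FN) x 100
    sensitivity = TP / (TP + FN) x 100
    specificity = TN / (TN + FP) x 100
    precision  = TP / (TP + FP) x 100
    F1         = 2 * sensitivity * precision / (sensitivity + precision)

    A zero denominator yields 0 and the metric name is recorded in
    ``undefined``.
    """
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    if min(c.tn, c.fp, c.fn, c.tp) < 0:
        raise ValueError("confusion counts must be non-negative")
    undefined: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return 100.0 * num / den

    acc = 100.0 * (c.tp + c.tn) / c.total
    sens = ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = ratio(c.tn, c.tn + c.fp, "specificity")
    prec = ratio(c.tp, c.tp + c.fp, "precision")
    if sens + prec == 0:
        undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2.0 * sens * prec / (sens + prec)
    return MetricsReport(accuracy=acc, sensitivity=sens, specificity=spec,
                         precision=prec, f1=f1, undefined=undefined)


def _fit_feature_context(
    X: np.ndarray,
    y: np.ndarray,
    spec: FeatureSelectionSpec,
    factor_ids: list[int],
    target: str,
    seed: int,
):
    if spec.mode == "all30":
        return None
    if spec.mode == "pca2":
        return fit_pca(X, n_components=2)
    if spec.ranking_source == "fixture":
        return get_fixture_ranking(target, k=spec.top_k)
    return rank_importance(X, y, seed=seed, factor_ids=factor_ids,
                           target=target)


def _splitter(cv: CVConfig):
    if cv.stratified:
        return StratifiedKFold(n_splits=cv.k, shuffle=True,
                               random_state=cv.seed)
    return KFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)


def _aggregate(folds: list[ConfusionCounts], cv: CVConfig) -> MetricsReport:
    if cv.aggregation == "pooled-counts":
        pooled = sum(folds[1:], folds[0])
        return compute_metrics(pooled)
    reports = [compute_metrics(c) for c in folds]
    undefined = sorted({m for r in reports for m in r.undefined})
    return MetricsReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        sensitivity=float(np.mean([r.sensitivity for r in reports])),
        specificity=float(np.mean([r.specificity for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        undefined=undefined,
    )


def cross_validate(
    estimator,
    X: np.ndarray,
    y: np.ndarray,
    cv: CVConfig,
    feature_spec: FeatureSelectionSpec | None = None,
    factor_ids: list[int] | None = None,
    target: str = "Hinselmann",
    balance: bool = True,
) -> MetricsReport:
    """Evaluate an unfitted classifier under k-fold CV with oversampling.

    ``estimator`` is any scikit-learn-style classifier (cloned per fold).
    Under ``fold_safe`` the training folds are oversampled and the feature
    context fitted on the balanced training data only; under
    ``paper_global`` balancing and feature fitting precede the split.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("cross_validate requires both classes present")
    if feature_spec is None:
        feature_spec = FeatureSelectionSpec(mode="all30")
    if factor_ids is None:
        factor_ids = list(range(1, X.shape[1] + 1))

    folds: list[ConfusionCounts] = []
    if cv.leakage_mode == "paper_global":
        if balance:
            bal = oversample(X, y, seed=cv.seed)
            X, y = bal.X, bal.y
        ctx = _fit_feature_context(X, y, feature_spec, factor_ids, target,
                                   cv.seed)
        Xf = select_features(X, feature_spec, ctx, factor_ids)
        for tr, te in _splitter(cv).split(Xf, y):
            if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
                raise ValueError("a fold is missing a class")
            model = clone(estimator).fit(Xf[tr], y[tr])
            folds.append(confusion_counts(y[te], model.predict(Xf[te])))
        return _aggregate(folds, cv)

    for tr, te in _splitter(cv).split(X, y):
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            raise ValueError("a fold is missing a class")
        Xtr, ytr = X[tr], y[tr]
        if balance:
            bal = oversample(Xtr, ytr, seed=cv.seed)
            Xtr, ytr = bal.X, bal.y
        ctx = _fit_feature_context(Xtr, ytr, feature_spec, factor_ids,
                                   target, cv.seed)
        Xtr_f = select_features(Xtr, feature_spec, ctx, factor_ids)
        Xte_f = select_features(X[te], feature_spec, ctx, factor_ids)
        model = clone(estimator).fit(Xtr_f, ytr)
        folds.append(confusion_counts(y[te], model.predict(Xte_f)))
    return _aggregate(folds, cv)


def enumerate_grid(
    targets=TARGETS,
    feature_modes=FEATURE_MODES,
    methods=METHODS,
    ranking_source: str = "fixture",
) -> list[ScenarioSpec]:
    """Deterministic Cartesian product target x mode x method.

    The default grid has 16 scenarios (target x mode) and 160 experiments
    (scenario x method).
    """
    return [
        ScenarioSpec(target=t,
                     feature_mode=FeatureSelectionSpec(
                         mode=m, ranking_source=ranking_source),
                     method=meth)
        for t in targets for m in feature_modes for meth in methods
    ]


def count_scenarios(grid: list[ScenarioSpec]) -> int:
    return len({s.scenario_key for s in grid})


def optimize_gamlp(
    X: np.ndarray,
    y: np.ndarray,
    ga_config: GAConfig,
    cv_k: int = 5,
    fitness_mode: str = "cv",
):
    """Run the GA over MLP hyperparameters on an already-prepared matrix.

    The matrix is expected to be balanced and feature-selected; fitness is
    the seeded cross-validated (or holdout) accuracy of each decoded
    network.
    """
    def fitness(genotype: MLPGenotype) -> float:
        return fitness_of(genotype, X, y, k=cv_k, seed=ga_config.seed,
                          mode=fitness_mode)

    return run_ga(ga_config, fitness)


def run_experiment(
    spec: ScenarioSpec,
    data: CleanDataset,
    cv: CVConfig,
    ga_config: GAConfig | None = None,
    fitness_mode: str = "cv",
) -> MetricsReport:
    """Evaluate one grid cell: a (target, feature mode, method) triple.

    Baseline methods are evaluated directly under :func:`cross_validate`.
    For GA-MLP the hyperparameter search is run first — on the balanced,
    feature-selected full dataset, matching the framework's balance-then-
    search ordering — and the best decoded network is then evaluated under
    the requested CV protocol.
    """
    y = data.y[spec.target]
    X = data.X
    factor_ids = data.retained_factor_ids

    if spec.method != "GA-MLP":
        est = baseline_estimator(spec.method, seed=cv.seed)
        return cross_validate(est, X, y, cv, feature_spec=spec.feature_mode,
                              factor_ids=factor_ids, target=spec.target)

    if ga_config is None:
        ga_config = GAConfig()
    bal = oversample(X, y, seed=ga_config.seed)
    ctx = _fit_feature_context(bal.X, bal.y, spec.feature_mode, factor_ids,
                               spec.target, ga_config.seed)
    Xsel = select_features(bal.X, spec.feature_mode, ctx, factor_ids)
    result = optimize_gamlp(Xsel, bal.y, ga_config, cv_k=cv.k,
                            fitness_mode=fitness_mode)
    best_cfg = MLPTrainConfig.from_genotype(result.best.genotype,
                                            seed=ga_config.seed)
    est = build_classifier(best_cfg)
    return cross_validate(est, X, y, cv, feature_spec=spec.feature_mode,
                          factor_ids=factor_ids, target=spec.target)
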