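"""Two-hidden-layer MLP training under the fixed regime used by the GA.

Every candidate network shares the same fixed training parameters —
learning rate 0.001, momentum 0.90 (SGD only), at most 200 iterations —
while the genotype supplies activation, solver and the two hidden-layer
sizes. The GA's fitness is the stratified k-fold cross-validated accuracy
of the network, as a percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier

from gamlp.ga import ACTIVATIONS, SOLVERS, MLPGenotype, decode


@dataclass
class MLPTrainConfig:
    activation: str = "relu"
    solver: str = "adam"
    h1: int = 10
    h2: int = 10
    learning_rate: float = 0.001
    momentum: float = 0.90
    max_iterations: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.solver not in SOLVERS:
            raise ValueError(f"unknown solver {self.solver!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    @classmethod
    def from_genotype(cls, genotype: MLPGenotype, seed: int = 0,
                      **overrides) -> "MLPTrainConfig":
        d = decode(genotype)
        return cls(activation=d.activation, solver=d.solver,
                   h1=d.h1, h2=d.h2, seed=seed, **overrides)


@dataclass
class TrainedMLP:
    model: MLPClassifier
    input_dim: int
    iterations_run: int
    converged: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"expected {self.input_dim} input columns, got {X.shape[1]}")
        return self.model.predict(X)


def build_classifier(config: MLPTrainConfig) -> MLPClassifier:
    """An unfitted scikit-learn MLP matching the fixed training regime.

    Momentum only applies to the SGD solver; L-BFGS and Adam ignore it
    (their update rules have no classical-momentum term).
    """
    return MLPClassifier(
        hidden_layer_sizes=(config.h1, config.h2),
        activation=config.activation,
        solver=config.solver,
        learning_rate_init=config.learning_rate,
        momentum=config.momentum,
        max_iter=config.max_iterations,
        random_state=config.seed,
    )


def train_mlp(config: MLPTrainConfig, X: np.ndarray, y: np.ndarray) -> TrainedMLP:
    """Train the configured network; deterministic given config.seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("train_mlp requires both classes present")
    if np.isnan(X).any():
        raise ValueError("train_mlp requires a complete (no-missing) matrix")
    clf = build_classifier(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    if not np.isfinite(clf.loss_):
        raise ValueError("training diverged: non-finite loss")
    return TrainedMLP(
        model=clf,
        input_dim=X.shape[1],
        iterations_run=clf.n_iter_,
        converged=clf.n_iter_ < config.max_iterations,
    )


def fitness_of(
    genotype: MLPGenotype,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    mode: str = "cv",
) -> float:
    """Accuracy percentage of the decoded network under seeded evaluation.

    ``mode="cv"`` (default) is mean accuracy over stratified k-fold
    cross-validation; ``mode="holdout:F"`` trains on 1-F of the data and
    scores a single stratified holdout of fraction F — a faster fitness
    for large search budgets.
    """
    y = np.asarray(y, dtype=int)
    if mode == "cv":
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        accs = []
        for tr, te in skf.split(X, y):
            net = train_mlp(MLPTrainConfig.from_genotype(genotype, seed=seed),
                            X[tr], y[tr])
            accs.append(accuracy_score(y[te], net.predict(X[te])))
        return 100.0 * float(np.mean(accs))
    if mode.startswith("holdout:"):
        frac = float(mode.split(":", 1)[1])
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=frac, stratify=y, random_state=seed)
        net = train_mlp(MLPTrainConfig.from_genotype(genotype, seed=seed),
                        Xtr, ytr)
        return 100.0 * float(accuracy_score(yte, net.predict(Xte)))
    raise ValueError(f"unknown fitness mode {mode!r}")
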