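"""Feature selection: 2-component PCA, all factors, and RF-importance top-k.

Four modes mirror the evaluation grid: ``pca2`` (project onto the two
leading principal components), ``all30`` (identity), and ``top18`` /
``top10`` (columns of the k factors with the highest random-forest Gini
importance). Top-k rankings can be recomputed from data or taken from the
packaged reference rankings shipped with the package.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier

FEATURE_MODE_NAMES = ("pca2", "all30", "top18", "top10")


@dataclass
class PCAModel:
    """Fitted principal-component projection.

    ``components`` is (p, k) with orthonormal columns ordered by decreasing
    explained variance; the eigen-sign convention fixes the largest-magnitude
    loading of each component to be positive, so fits are reproducible
    across platforms.
    """

    mean: np.ndarray                # (p,)
    components: np.ndarray          # (p, k)
    explained_variance: np.ndarray  # (k,) descending

    def to_json(self) -> str:
        return json.dumps({
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
        })

    @classmethod
    def from_json(cls, s: str) -> "PCAModel":
        d = json.loads(s)
        return cls(mean=np.asarray(d["mean"]),
                   components=np.asarray(d["components"]),
                   explained_variance=np.asarray(d["explained_variance"]))


@dataclass
class ImportanceRanking:
    """Factors ordered by decreasing random-forest importance.

    ``ordered_factor_ids`` uses the original 1-based factor numbering;
    ``scores`` is None for packaged reference rankings, which print the
    order but not the importance values.
    """

    target: str
    ordered_factor_ids: list[int]
    scores: np.ndarray | None = None


@dataclass
class FeatureSelectionSpec:
    mode: str                        # one of FEATURE_MODE_NAMES
    ranking_source: str = "fixture"  # "fixture" | "recompute"

    def __post_init__(self):
        if self.mode not in FEATURE_MODE_NAMES:
            raise ValueError(f"unknown feature mode {self.mode!r}")
        if self.ranking_source not in ("fixture", "recompute"):
            raise ValueError(f"unknown ranking source {self.ranking_source!r}")

    @property
    def top_k(self) -> int | None:
        return {"top18": 18, "top10": 10}.get(self.mode)


def fit_pca(X: np.ndarray, n_components: int = 2) -> PCAModel:
    """Fit a principal-component projection onto ``n_components`` axes.

    Components are the top eigenvectors of the column-centered covariance
    matrix, ordered by eigenvalue. If the data has rank below
    ``n_components``, a warning is issued and zero-variance components pad
    the model out to the requested width.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_pca needs a 2-D matrix with at least 2 rows")
    if X.shape[1] < n_components:
        raise ValueError(
            f"fit_pca: {X.shape[1]} columns < n_components={n_components}")
    k_fit = min(n_components, X.shape[0] - 1, X.shape[1])
    p = PCA(n_components=k_fit, svd_solver="full").fit(X)
    comps = p.components_.copy()            # (k_fit, p)
    var = p.explained_variance_.copy()
    # Treat numerically-zero variance directions as rank deficiency.
    nz = var > max(var[0], 0.0) * 1e-12 if var.size else var > 0
    if not nz.all() or k_fit < n_components:
        warnings.warn(
            "data rank below requested components; padding with "
            "zero-variance components", RuntimeWarning)
        comps, var = comps[nz], var[nz]
        pad = n_components - comps.shape[0]
        comps = np.vstack([comps, np.zeros((pad, X.shape[1]))])
        var = np.concatenate([var, np.zeros(pad)])
    # Sign convention: largest-|loading| entry positive per component.
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] *= -1
    return PCAModel(mean=X.mean(axis=0), components=comps.T,
                    explained_variance=var)


def transform_pca(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project rows of X into the fitted component space: (X - mean) @ W."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"transform_pca: X has {X.shape[1]} columns, model expects "
            f"{model.mean.shape[0]}")
    return (X - model.mean) @ model.components


def rank_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
    factor_ids: list[int] | None = None,
    target: str = "",
) -> ImportanceRanking:
    """Rank factors by mean Gini-impurity decrease over a seeded forest.

    Ties are broken by the smaller factor number, making the ranking
    deterministic for a fixed seed.
    """
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("rank_importance requires both classes present")
    if factor_ids is None:
        factor_ids = list(range(1, X.shape[1] + 1))
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(X, y)
    scores = rf.feature_importances_
    order = sorted(range(len(factor_ids)),
                   key=lambda j: (-scores[j], factor_ids[j]))
    return ImportanceRanking(
        target=target,
        ordered_factor_ids=[factor_ids[j] for j in order],
        scores=scores[order],
    )


def _load_fixture_table() -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    text = (resources.files("gamlp") / "data" / "rf_rankings.csv").read_text()
    lines = text.strip().splitlines()[1:]
    rows = [ln.split(",") for ln in lines]
    for target, rank, fid in rows:
        out.setdefault(target, []).append((int(rank), int(fid)))
    return {t: [fid for _, fid in sorted(v)] for t, v in out.items()}


_FIXTURES: dict[str, list[int]] | None = None


def get_fixture_ranking(target: str, k: int = 18) -> ImportanceRanking:
    """Packaged reference top-k importance ranking for a screening test.

    ``k`` is 10 or 18; the top-10 list is by construction the prefix of the
    top-18 list for every target.
    """
    global _FIXTURES
    if _FIXTURES is None:
        _FIXTURES = _load_fixture_table()
    if target not in _FIXTURES:
        raise ValueError(
            f"unknown target {target!r}; expected one of {sorted(_FIXTURES)}")
    if k not in (10, 18):
        raise ValueError(f"fixture rankings exist for k in (10, 18), got {k}")
    return ImportanceRanking(target=target,
                             ordered_factor_ids=_FIXTURES[target][:k])


def select_features(
    X: np.ndarray,
    spec: FeatureSelectionSpec,
    context: PCAModel | ImportanceRanking | None = None,
    factor_ids: list[int] | None = None,
) -> np.ndarray:
    """Apply a feature-selection mode to a factor matrix.

    ``context`` must be a fitted :class:`PCAModel` for ``pca2`` or an
    :class:`ImportanceRanking` for the top-k modes; ``factor_ids`` maps X's
    columns to original factor numbers (defaults to 1..p).
    """
    if spec.mode == "all30":
        return X
    if spec.mode == "pca2":
        if not isinstance(context, PCAModel):
            raise ValueError("pca2 mode needs a fitted PCAModel context")
        return transform_pca(context, X)
    k = spec.top_k
    if not isinstance(context, ImportanceRanking):
        raise ValueError(f"{spec.mode} mode needs an ImportanceRanking context")
    if len(context.ordered_factor_ids) < k:
        raise ValueError(
            f"ranking has {len(context.ordered_factor_ids)} factors, "
            f"need {k}")
    if factor_ids is None:
        factor_ids = list(range(1, X.shape[1] + 1))
    pos = {fid: j for j, fid in enumerate(factor_ids)}
    missing = [f for f in context.ordered_factor_ids[:k] if f not in pos]
    if missing:
        raise ValueError(
            f"ranking references factor ids absent from the data: {missing}")
    cols = [pos[fid] for fid in context.ordered_factor_ids[:k]]
    return X[:, cols]
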