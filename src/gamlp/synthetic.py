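"""Synthetic risk-factor tables with a controllable planted signal.

The generator emulates the schema of the source screening dataset: ~30
mixed binary/continuous patient factors (age-like, years-of-exposure-like),
four binary screening-test targets at low prevalence (4.5-9.4%), optional
missing cells marked "?", and a logistic planted signal linking a chosen
factor subset to each label. It does NOT attempt to reproduce the real
data's marginal distributions or correlation structure — only its shape
and difficulty regime — so the pipeline is testable without any download.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from gamlp.data_io import RawTable

DEFAULT_TARGETS = ("Hinselmann", "Schiller", "Cytology", "Biopsy")

#: Fraction of positives per screening test in the emulated dataset.
DEFAULT_PREVALENCE = {
    "Hinselmann": 0.045,
    "Schiller": 0.094,
    "Cytology": 0.058,
    "Biopsy": 0.067,
}

#: Continuous factors in the emulated 32-factor schema (ages, counts,
#: years of exposure); everything else is a 0/1 indicator.
CONTINUOUS_FACTOR_IDS = (1, 2, 3, 4, 6, 7, 9, 11, 13, 26, 27, 28)


def _default_signal(n_factors: int) -> dict[str, tuple[list[int], list[float]]]:
    # Age, first-intercourse age and contraceptive-years drive every test,
    # echoing the factors real importance rankings put on top.
    ids = [f for f in (1, 3, 9) if f <= n_factors]
    return {t: (ids, [1.0] * len(ids)) for t in DEFAULT_TARGETS}


@dataclass
class SyntheticSpec:
    n_rows: int = 668
    n_factors: int = 30
    binary_factor_ids: tuple[int, ...] | None = None  # None -> schema default
    prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))
    signal_factors: dict[str, tuple[list[int], list[float]]] | None = None
    noise_scale: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 2 or self.n_factors < 1:
            raise ValueError("need n_rows >= 2 and n_factors >= 1")
        for t, p in self.prevalence.items():
            if not 0 < p < 1:
                raise ValueError(f"prevalence for {t} must lie in (0, 1)")
            n_pos = round(self.n_rows * p)
            if n_pos == 0 or n_pos == self.n_rows:
                raise ValueError(
                    f"prevalence {p} for {t} rounds to a single-class label "
                    f"at n_rows={self.n_rows}")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.signal_factors is not None:
            for t, (ids, effects) in self.signal_factors.items():
                if len(ids) != len(effects):
                    raise ValueError(f"{t}: ids and effects differ in length")
                if any(not 1 <= f <= self.n_factors for f in ids):
                    raise ValueError(
                        f"{t}: signal factors must lie in 1..{self.n_factors}")

    def resolved_binary_ids(self) -> set[int]:
        if self.binary_factor_ids is not None:
            return set(self.binary_factor_ids)
        return set(range(1, self.n_factors + 1)) - set(CONTINUOUS_FACTOR_IDS)

    def resolved_signal(self) -> dict[str, tuple[list[int], list[float]]]:
        if self.signal_factors is not None:
            return self.signal_factors
        return _default_signal(self.n_factors)


def _exact_count_labels(
    logits: np.ndarray, n_pos: int, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli labels from logits, then label swaps to an exact count.

    Positives are removed from (added to) the rows with the lowest
    (highest) model probability first, so the planted signal survives the
    adjustment.
    """
    p = 1.0 / (1.0 + np.exp(-logits))
    y = (rng.random(len(p)) < p).astype(int)
    excess = int(y.sum()) - n_pos
    if excess > 0:
        pos = np.flatnonzero(y == 1)
        y[pos[np.argsort(p[pos])[:excess]]] = 0
    elif excess < 0:
        neg = np.flatnonzero(y == 0)
        y[neg[np.argsort(-p[neg])[:-excess]]] = 1
    return y


def generate(spec: SyntheticSpec) -> RawTable:
    """Generate a screening-schema table per the spec; seed-reproducible.

    Continuous factors are right-skewed and non-negative (lognormal
    age-like, gamma years-like); binary factors are Bernoulli indicators.
    Each target follows a logistic model on its standardized signal
    factors, adjusted by label swaps so the positive count equals
    round(n_rows * prevalence) exactly. Missing cells (NaN in the returned
    table, "?" in CSV form) are injected at ``missing_rate`` into factor
    columns only.
    """
    rng = np.random.default_rng(spec.seed)
    binary_ids = spec.resolved_binary_ids()
    n, p = spec.n_rows, spec.n_factors

    X = np.empty((n, p))
    for fid in range(1, p + 1):
        j = fid - 1
        if fid in binary_ids:
            X[:, j] = rng.random(n) < 0.15
        elif fid == 1:
            X[:, j] = np.round(rng.lognormal(3.3, 0.3, size=n))   # age-like
        else:
            X[:, j] = np.round(
                rng.gamma(1.5, 2.0 * spec.noise_scale, size=n), 1)  # years-like

    signal = spec.resolved_signal()
    targets, T = [], []
    for t, prev in spec.prevalence.items():
        ids, effects = signal.get(t, ([], []))
        logits = np.full(n, np.log(prev / (1 - prev)))
        for fid, beta in zip(ids, effects):
            col = X[:, fid - 1]
            sd = col.std()
            z = (col - col.mean()) / sd if sd > 0 else np.zeros(n)
            logits = logits + beta * z
        y = _exact_count_labels(logits, round(n * prev), rng)
        targets.append(t)
        T.append(y.astype(float))

    if spec.missing_rate > 0:
        mask = rng.random(X.shape) < spec.missing_rate
        X[mask] = np.nan

    values = np.column_stack([X] + T)
    factor_names = [f"factor_{i}" for i in range(1, p + 1)]
    return RawTable(values=values, factor_names=factor_names,
                    target_names=targets)


def to_csv(table: RawTable, path=None, missing_marker: str = "?") -> str | None:
    """Write a RawTable in the dialect ``data_io.read_table`` reads."""
    buf = io.StringIO()
    buf.write(",".join(table.factor_names + table.target_names) + "\n")
    for row in table.values:
        cells = [missing_marker if np.isnan(v) else format(v, "g")
                 for v in row]
        buf.write(",".join(cells) + "\n")
    text = buf.getvalue()
    if path is None:
        return text
    with open(path, "w") as fh:
        fh.write(text)
    return None


def make_separable(
    n_rows: int,
    n_factors: int = 2,
    margin: float = 6.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two near-Gaussian clouds with centers ``margin`` apart.

    Labels are exactly balanced (n_rows must be even). ``margin`` is the
    center-to-center distance along a random unit direction; the noise
    component along that direction is a standard normal truncated at
    +/-2.5, so any margin above 5 leaves a genuine gap between the classes
    (linear separability is guaranteed, not just likely), while margin 0
    gives pure class overlap and chance-level accuracy.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if n_rows % 2:
        raise ValueError("n_rows must be even for exactly balanced labels")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=n_factors)
    u /= np.linalg.norm(u)
    y = np.repeat([0, 1], n_rows // 2)
    X = rng.normal(size=(n_rows, n_factors))
    along = truncnorm.rvs(-2.5, 2.5, size=n_rows, random_state=rng)
    X += (along - X @ u)[:, None] * u          # replace the along-u component
    X += ((y - 0.5) * margin)[:, None] * u     # shift classes to +/- margin/2
    perm = rng.permutation(n_rows)
    return X[perm], y[perm]
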