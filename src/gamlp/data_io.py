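"""Reading, preprocessing and class-balancing of risk-factor tables.

The expected input is a patient-by-factor CSV in the layout of the UCI
cervical-cancer risk-factor dataset: a header row, 32 factor columns
followed by 4 binary target columns (Hinselmann, Schiller, Cytology,
Biopsy), and ``?`` marking cells the patient declined to answer.
Smaller tables in the same dialect (header + factor columns + trailing
target columns) are accepted as well, which is what the synthetic
generator emits.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: 1-based factor ids dropped by default: the two "time since diagnosis"
#: factors that are almost entirely missing in the source data.
DEFAULT_DROP_FACTORS = (27, 28)

#: Prevalence (fraction of positives) of each screening test reported for
#: the preprocessed source dataset; used only to warn when a supplied real
#: table deviates from the expected class balance.
EXPECTED_PREVALENCE = {
    "Hinselmann": 0.045,
    "Schiller": 0.094,
    "Citology": 0.058,
    "Cytology": 0.058,
    "Biopsy": 0.067,
}


@dataclass
class RawTable:
    """A parsed CSV table: numeric cells with NaN marking missing values."""

    values: np.ndarray            # (n_rows, n_cols) float, NaN = missing
    factor_names: list[str]       # ordered factor column names
    target_names: list[str]       # ordered target column names

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    @property
    def factor_values(self) -> np.ndarray:
        return self.values[:, : self.n_factors]

    @property
    def target_values(self) -> np.ndarray:
        return self.values[:, self.n_factors:]


@dataclass
class PreprocessReport:
    rows_before: int
    rows_after: int
    dropped_factor_ids: list[int]
    normalized_factor_ids: list[int]
    binary_factor_ids: list[int]
    prevalence: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rows_before": self.rows_before,
            "rows_after": self.rows_after,
            "dropped_factor_ids": self.dropped_factor_ids,
            "normalized_factor_ids": self.normalized_factor_ids,
            "binary_factor_ids": self.binary_factor_ids,
            "prevalence": self.prevalence,
            "warnings": self.warnings,
        }


@dataclass
class CleanDataset:
    """Fully numeric dataset: no missing cells, one binary vector per target.

    ``retained_factor_ids`` carries the original 1-based factor numbering so
    that feature rankings expressed in those ids can be mapped to columns.
    """

    X: np.ndarray                     # (n, p) float, no NaN
    y: dict[str, np.ndarray]          # target name -> (n,) int array in {0,1}
    retained_factor_ids: list[int]
    factor_names: list[str]

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def column_of(self, factor_id: int) -> int:
        """Column index in X of a 1-based original factor id."""
        return self.retained_factor_ids.index(factor_id)


@dataclass
class BalancedDataset:
    """A single-target dataset after random oversampling to exact balance."""

    X: np.ndarray
    y: np.ndarray
    provenance: np.ndarray  # source-row index of every row (duplicates allowed)


def read_table(
    path,
    missing_marker: str = "?",
    n_targets: int = 4,
) -> RawTable:
    """Parse a CSV risk-factor table.

    The last ``n_targets`` header columns are treated as targets, the rest
    as factors. Every cell must be numeric or equal to ``missing_marker``.

    Raises
    ------
    ValueError
        On an empty file, a row whose width differs from the header, or a
        non-numeric non-missing cell (the offending row is named).
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: no data rows (file is empty)")
        header = [h.strip() for h in header]
        if len(header) <= n_targets:
            raise ValueError(
                f"{path}: header has {len(header)} columns, "
                f"need more than {n_targets}"
            )
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: row {lineno} has {len(row)} cells, "
                    f"expected {len(header)}"
                )
            parsed = []
            for colname, cell in zip(header, row):
                cell = cell.strip()
                if cell == missing_marker or cell == "":
                    parsed.append(math.nan)
                else:
                    try:
                        parsed.append(float(cell))
                    except ValueError:
                        raise ValueError(
                            f"{path}: row {lineno}, column {colname!r}: "
                            f"cell {cell!r} is neither numeric nor the "
                            f"missing marker {missing_marker!r}"
                        ) from None
            rows.append(parsed)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    values = np.asarray(rows, dtype=float)
    factor_names = header[:-n_targets]
    target_names = header[-n_targets:]
    logger.info(
        "read %s: %d rows, %d factors, %d targets",
        path, values.shape[0], len(factor_names), len(target_names),
    )
    return RawTable(values=values, factor_names=factor_names,
                    target_names=target_names)


def _is_binary(col: np.ndarray) -> bool:
    vals = np.unique(col[~np.isnan(col)])
    return vals.size > 0 and np.all(np.isin(vals, (0.0, 1.0)))


def preprocess(
    raw: RawTable,
    drop_factors=DEFAULT_DROP_FACTORS,
    normalize: bool = True,
) -> tuple[CleanDataset, PreprocessReport]:
    """Drop heavily missing factors, filter incomplete rows, scale.

    Factor ids in ``drop_factors`` (1-based) are removed, then every row
    with a missing value in any retained factor or target column is
    removed. If ``normalize``, each continuous factor is min-max scaled to
    [0, 1] (constant columns map to all-zero); binary 0/1 factors pass
    through untouched.
    """
    drop = set(int(f) for f in drop_factors)
    bad = drop - set(range(1, raw.n_factors + 1))
    if bad:
        raise ValueError(f"drop_factors not in 1..{raw.n_factors}: {sorted(bad)}")
    if not raw.target_names:
        raise ValueError("table has no target columns")

    keep_ids = [i for i in range(1, raw.n_factors + 1) if i not in drop]
    keep_cols = [i - 1 for i in keep_ids]
    F = raw.factor_values[:, keep_cols]
    T = raw.target_values
    complete = ~np.isnan(F).any(axis=1) & ~np.isnan(T).any(axis=1)
    rows_before = raw.n_rows
    F, T = F[complete], T[complete]
    if F.shape[0] == 0:
        raise ValueError("preprocessing removed every row")

    warnings: list[str] = []
    binary_ids, normalized_ids = [], []
    X = F.astype(float).copy()
    for j, fid in enumerate(keep_ids):
        col = X[:, j]
        if _is_binary(col):
            binary_ids.append(fid)
            continue
        if normalize:
            lo, hi = col.min(), col.max()
            X[:, j] = 0.0 if hi == lo else (col - lo) / (hi - lo)
            normalized_ids.append(fid)

    y = {}
    prevalence = {}
    for k, name in enumerate(raw.target_names):
        vec = T[:, k]
        if not _is_binary(vec):
            raise ValueError(f"target column {name!r} is not binary 0/1")
        y[name] = vec.astype(int)
        prevalence[name] = float(vec.mean())
        # prevalence reference values only apply to the full 32-factor schema
        expected = EXPECTED_PREVALENCE.get(name) if raw.n_factors == 32 else None
        if expected is not None and abs(prevalence[name] - expected) > 0.005:
            msg = (f"target {name}: prevalence {prevalence[name]:.3f} differs "
                   f"from the expected {expected:.3f}")
            warnings.append(msg)
            logger.warning(msg)

    report = PreprocessReport(
        rows_before=rows_before,
        rows_after=X.shape[0],
        dropped_factor_ids=sorted(drop),
        normalized_factor_ids=normalized_ids,
        binary_factor_ids=binary_ids,
        prevalence=prevalence,
        warnings=warnings,
    )
    logger.info("preprocess: %d -> %d rows, dropped factors %s",
                rows_before, X.shape[0], sorted(drop))
    clean = CleanDataset(
        X=X, y=y, retained_factor_ids=keep_ids,
        factor_names=[raw.factor_names[i] for i in keep_cols],
    )
    return clean, report


def oversample(X: np.ndarray, y: np.ndarray, seed: int) -> BalancedDataset:
    """Random oversampling: duplicate minority rows until classes balance.

    Majority rows are untouched; the minority class gains uniformly
    resampled (with replacement) copies of its own rows. Deterministic
    given ``seed``. Already-balanced input is returned unchanged.
    """
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("oversample requires both classes present")
    if counts[0] == counts[1]:
        return BalancedDataset(X=X.copy(), y=y.copy(),
                               provenance=np.arange(len(y)))
    minority = classes[np.argmin(counts)]
    deficit = int(abs(counts[0] - counts[1]))
    rng = np.random.default_rng(seed)
    minority_idx = np.flatnonzero(y == minority)
    extra = rng.choice(minority_idx, size=deficit, replace=True)
    provenance = np.concatenate([np.arange(len(y)), extra])
    return BalancedDataset(X=X[provenance], y=y[provenance],
                           provenance=provenance)
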