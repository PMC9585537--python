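"""Tabular clinical data handling.

Reads and writes the UCI heart-disease "processed" CSV dialect
(comma-separated, no header, ``?`` for missing, integer target 0-4 in the
last column), binarizes targets, imputes missing entries, standardizes
features, and generates synthetic tables with the same statistical
structure (two class-conditional Gaussians, optional injected outliers and
missing cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PROCESSED_14_NAMES",
    "CATEGORICAL_NAMES",
    "FeatureTable",
    "SyntheticSpec",
    "read_uci_heart",
    "write_uci_heart",
    "binarize_target",
    "impute_missing",
    "standardize",
    "generate_synthetic",
    "stratified_split",
]

#: Attribute names of the standard 14-column "processed" dialect
#: (13 features; the target is carried separately on FeatureTable.y).
PROCESSED_14_NAMES: tuple[str, ...] = (
    "age",
    "sex",
    "cp",
    "trestbps",
    "chol",
    "fbs",
    "restecg",
    "thalach",
    "exang",
    "oldpeak",
    "slope",
    "ca",
    "thal",
)

#: Built-in schema of categorical/ordinal-coded attributes; imputation uses
#: the per-column mode for these (median on codes is meaningless).
CATEGORICAL_NAMES: frozenset[str] = frozenset(
    {"sex", "cp", "fbs", "restecg", "exang", "slope", "ca", "thal"}
)

# 1-based positions of the standard 14 attributes inside the 76-column raw
# record layout (age..num); used to subset the raw_76 dialect.
_RAW76_POSITIONS: tuple[int, ...] = (3, 4, 9, 10, 12, 16, 19, 32, 38, 40, 41, 44, 51, 58)


@dataclass
class FeatureTable:
    """Samples-by-attributes table with labels and an explicit missing mask.

    Attributes
    ----------
    X : (n, J) float array; entries under ``missing`` are NaN until imputed.
    y : (n,) int array; raw 0-4 target codes or binarized 0/1 labels.
    missing : (n, J) bool array, True where the source had a ``?``.
    names : attribute identifiers, length J.
    outlier_flags : optional (n,) bool provenance marker set by
        :func:`generate_synthetic` for injected outlier rows.
    """

    X: np.ndarray
    y: np.ndarray
    missing: np.ndarray
    names: tuple[str, ...]
    outlier_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.names = tuple(self.names)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, j = self.X.shape
        if n < 1 or j < 1:
            raise ValueError("table must have at least one sample and one attribute")
        if self.y.shape != (n,):
            raise ValueError(f"y has shape {self.y.shape}, expected ({n},)")
        if self.missing.shape != (n, j):
            raise ValueError("missing mask shape must match X")
        if len(self.names) != j:
            raise ValueError("names length must equal the number of attributes")
        if self.outlier_flags is not None:
            self.outlier_flags = np.asarray(self.outlier_flags, dtype=bool)
            if self.outlier_flags.shape != (n,):
                raise ValueError("outlier_flags length must equal n")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def take(self, idx: np.ndarray) -> "FeatureTable":
        """Row subset preserving all aligned per-row arrays."""
        idx = np.asarray(idx)
        flags = None if self.outlier_flags is None else self.outlier_flags[idx]
        return FeatureTable(
            X=self.X[idx],
            y=self.y[idx],
            missing=self.missing[idx],
            names=self.names,
            outlier_flags=flags,
        )


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for :func:`generate_synthetic`."""

    n_per_class: tuple[int, int]
    means: tuple[np.ndarray, np.ndarray]
    covariances: tuple[np.ndarray, np.ndarray]
    outlier_fraction: float = 0.0
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_class) != 2 or any(int(n) <= 0 for n in self.n_per_class):
            raise ValueError("n_per_class must be two positive integers")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        j = len(np.asarray(self.means[0]))
        for m in self.means:
            if len(np.asarray(m)) != j:
                raise ValueError("class means must share one dimensionality")
        for c in self.covariances:
            c = np.asarray(c, dtype=float)
            if c.shape != (j, j):
                raise ValueError("covariances must be JxJ")


def _parse_field(tok: str, row_no: int) -> tuple[float, bool]:
    tok = tok.strip()
    if tok == "?" or tok == "":
        return np.nan, True
    try:
        return float(tok), False
    except ValueError as exc:
        raise ValueError(f"row {row_no}: unparseable field {tok!r}") from exc


def read_uci_heart(path: str | Path, dialect: str = "processed_14") -> FeatureTable:
    """Read a UCI heart-disease CSV file.

    ``processed_14``: 14 comma-separated columns per row, target last.
    ``raw_76``: 76 comma-separated columns per row; only the standard
    14-attribute subset is retained.

    Raises ``ValueError`` on an empty file or any row with the wrong field
    count (reported with its 1-based row number); no row is silently dropped.
    """
    if dialect not in ("processed_14", "raw_76"):
        raise ValueError(f"unknown dialect {dialect!r}")
    expected = 14 if dialect == "processed_14" else 76
    rows: list[list[str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != expected:
                raise ValueError(
                    f"row {row_no}: expected {expected} fields, got {len(fields)}"
                )
            if dialect == "raw_76":
                fields = [fields[p - 1] for p in _RAW76_POSITIONS]
            rows.append(fields)
    if not rows:
        raise ValueError(f"empty file: {path}")

    n, width = len(rows), 14
    X = np.empty((n, width - 1))
    missing = np.zeros((n, width - 1), dtype=bool)
    y = np.empty(n, dtype=int)
    for i, fields in enumerate(rows):
        for j in range(width - 1):
            X[i, j], missing[i, j] = _parse_field(fields[j], i + 1)
        target, tgt_missing = _parse_field(fields[-1], i + 1)
        if tgt_missing:
            raise ValueError(f"row {i + 1}: missing target value")
        y[i] = int(target)
    return FeatureTable(X=X, y=y, missing=missing, names=PROCESSED_14_NAMES)


def write_uci_heart(table: FeatureTable, path: str | Path) -> None:
    """Write the processed_14 dialect; missing entries rendered as ``?``."""

    def fmt(v: float) -> str:
        return repr(int(v)) if float(v).is_integer() else repr(float(v))

    with open(path, "w", encoding="utf-8") as fh:
        for i in range(table.n_samples):
            fields = [
                "?" if table.missing[i, j] else fmt(table.X[i, j])
                for j in range(table.n_features)
            ]
            fields.append(str(int(table.y[i])))
            fh.write(",".join(fields) + "\n")


def binarize_target(y_raw: np.ndarray | Sequence[int]) -> np.ndarray:
    """Map raw 0-4 target codes to binary labels: 0 -> 0, {1,2,3,4} -> 1."""
    y = np.asarray(y_raw, dtype=int)
    bad = ~np.isin(y, (0, 1, 2, 3, 4))
    if bad.any():
        raise ValueError(f"target values outside 0..4: {sorted(set(y[bad].tolist()))}")
    return (y > 0).astype(int)


def impute_missing(table: FeatureTable, strategy: str = "mode_for_categorical") -> FeatureTable:
    """Fill missing entries with a per-column statistic over observed entries.

    ``median`` uses the column median everywhere; ``mode_for_categorical``
    uses the mode for columns in the built-in categorical schema and the
    median elsewhere.  A fully-missing column is rejected by name.
    """
    if strategy not in ("median", "mode_for_categorical"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if not table.missing.any():
        return table
    X = table.X.copy()
    for j, name in enumerate(table.names):
        mask = table.missing[:, j]
        if not mask.any():
            continue
        observed = X[~mask, j]
        if observed.size == 0:
            raise ValueError(f"column {name!r} is fully missing")
        if strategy == "mode_for_categorical" and name in CATEGORICAL_NAMES:
            values, counts = np.unique(observed, return_counts=True)
            fill = values[np.argmax(counts)]
        else:
            fill = float(np.median(observed))
        X[mask, j] = fill
    return replace(table, X=X, missing=np.zeros_like(table.missing))


def standardize(
    X: np.ndarray, mean: np.ndarray | None = None, std: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column z-score. Fit on one split (mean/std None) and reuse on another."""
    X = np.asarray(X, dtype=float)
    if mean is None:
        mean = X.mean(axis=0)
    if std is None:
        std = X.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    return (X - mean) / std, mean, std


#: Covariance inflation factor applied to injected outlier rows.
OUTLIER_COV_INFLATION = 25.0


def generate_synthetic(spec: SyntheticSpec) -> FeatureTable:
    """Draw a two-class Gaussian table per ``spec``.

    Rows are class-conditional Gaussian draws.  ``outlier_fraction`` of rows
    are replaced by draws from the same class mean with covariance inflated
    by a factor of 25 and flagged in ``outlier_flags`` (labels preserved).
    ``missing_fraction`` of cells are masked uniformly at random (masked
    entries are NaN).  Identical seeds give identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    means = [np.asarray(m, dtype=float) for m in spec.means]
    covs = [np.asarray(c, dtype=float) for c in spec.covariances]
    j = means[0].size
    chols = []
    for c in covs:
        try:
            chols.append(np.linalg.cholesky(c))
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance matrix is not positive definite") from exc

    blocks, labels = [], []
    for cls, (n_c, mu, chol) in enumerate(zip(spec.n_per_class, means, chols)):
        z = rng.standard_normal((int(n_c), j))
        blocks.append(mu + z @ chol.T)
        labels.append(np.full(int(n_c), cls, dtype=int))
    X = np.vstack(blocks)
    y = np.concatenate(labels)
    n = X.shape[0]

    flags = np.zeros(n, dtype=bool)
    n_out = int(round(spec.outlier_fraction * n))
    if n_out > 0:
        idx = rng.choice(n, size=n_out, replace=False)
        scale = np.sqrt(OUTLIER_COV_INFLATION)
        for i in idx:
            cls = y[i]
            X[i] = means[cls] + scale * (rng.standard_normal(j) @ chols[cls].T)
        flags[idx] = True

    missing = np.zeros((n, j), dtype=bool)
    n_missing = int(round(spec.missing_fraction * n * j))
    if n_missing > 0:
        flat = rng.choice(n * j, size=n_missing, replace=False)
        missing[np.unravel_index(flat, (n, j))] = True
        X = X.copy()
        X[missing] = np.nan

    names = tuple(f"f{k}" for k in range(j))
    return FeatureTable(X=X, y=y, missing=missing, names=names, outlier_flags=flags)


def stratified_split(
    y: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Return (train_idx, test_idx), stratified by label, seeded."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_test = int(round(test_fraction * idx.size))
        n_test = min(max(n_test, 1), idx.size - 1) if idx.size > 1 else 0
        test_parts.append(idx[:n_test])
        train_parts.append(idx[n_test:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    return train, test
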