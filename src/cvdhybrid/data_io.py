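"""Reading, cleaning and splitting UCI-heart-style tabular clinical data.

Two file dialects are supported natively: the processed-Cleveland format
(comma-separated, 13 attributes plus a 0-4 severity label, ``?`` marking
missing cells) and the Statlog-heart format (whitespace-separated, labels
1 = absence / 2 = presence).  Cleaning follows a strict row-deletion policy:
rows containing a missing marker are dropped, exact duplicate rows are
dropped, and the Cleveland severity label is binarized at > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawTable",
    "CleanTable",
    "SplitSpec",
    "PreprocessReport",
    "read_uci_cleveland",
    "read_statlog",
    "preprocess",
    "minmax_normalize",
    "train_test_split",
    "CLEVELAND_ATTRIBUTES",
]

#: Canonical attribute names of the 13-attribute processed Cleveland table.
CLEVELAND_ATTRIBUTES = [
    "age", "sex", "cp", "trestbps", "chol", "fbs", "restecg",
    "thalach", "exang", "oldpeak", "slope", "ca", "thal",
]


@dataclass
class RawTable:
    """Parsed but uncleaned records; the label is the last column."""

    rows: list
    attribute_names: list
    missing_marker: str = "?"

    def __post_init__(self):
        if not self.rows:
            raise ValueError("no records")
        arity = len(self.attribute_names) + 1
        for i, row in enumerate(self.rows):
            if len(row) != arity:
                raise ValueError(
                    f"row {i + 1}: expected {arity} columns, got {len(row)}"
                )
        if arity < 2:
            raise ValueError("need at least one attribute plus a label")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_rows, arity) mask of cells equal to the missing marker."""
        m = np.zeros((len(self.rows), len(self.rows[0])), dtype=bool)
        for i, row in enumerate(self.rows):
            for j, cell in enumerate(row):
                if isinstance(cell, str) and cell == self.missing_marker:
                    m[i, j] = True
        return m


@dataclass
class CleanTable:
    """Numeric sample-by-attribute matrix with binary labels."""

    X: np.ndarray
    y: np.ndarray
    attribute_names: list

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y shapes inconsistent")
        if not np.all(np.isin(self.y, [0, 1])):
            raise ValueError("labels must be binary {0,1}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("CleanTable may not contain missing entries")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.X.shape[1]


@dataclass
class SplitSpec:
    """Train/test split request: fraction of rows for training, RNG seed."""

    train_fraction: float = 0.9
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class PreprocessReport:
    missing_dropped: int = 0
    duplicates_dropped: int = 0
    n_kept: int = 0
    single_class: bool = False
    warnings: list = field(default_factory=list)


def _parse_lines(lines, sep, path, missing_marker):
    rows = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        cells = line.split(sep) if sep else line.split()
        cells = [c.strip() for c in cells]
        if len(cells) != 14:
            raise ValueError(
                f"{path}: line {lineno}: expected 14 columns, got {len(cells)}"
            )
        row = []
        for c in cells:
            if c == missing_marker:
                row.append(c)
            else:
                try:
                    row.append(float(c))
                except ValueError:
                    row.append(c)
        rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no records")
    return rows


def read_uci_cleveland(path, missing_marker: str = "?") -> RawTable:
    """Read a processed-Cleveland file (comma-separated, 14 columns).

    ``?`` cells are preserved verbatim as missing markers; the final column
    is the 0-4 severity label.
    """
    with open(path) as fh:
        rows = _parse_lines(fh, ",", path, missing_marker)
    return RawTable(rows, list(CLEVELAND_ATTRIBUTES), missing_marker)


def read_statlog(path) -> RawTable:
    """Read a Statlog-heart file (whitespace-separated, labels 1/2).

    Labels are remapped 1 -> 0 (absence) and 2 -> 1 (presence).
    """
    with open(path) as fh:
        rows = _parse_lines(fh, None, path, "?")
    for i, row in enumerate(rows):
        lab = row[-1]
        if lab not in (1.0, 2.0):
            raise ValueError(f"row {i + 1}: Statlog label must be 1 or 2, got {lab!r}")
        row[-1] = lab - 1.0
    return RawTable(rows, list(CLEVELAND_ATTRIBUTES), "?")


def preprocess(raw: RawTable, label_binarize_threshold: float = 0.0):
    """Drop missing-valued and duplicate rows, binarize the label.

    Rows containing the missing marker anywhere are removed first; then
    exact duplicates (all attribute values AND label) keep only their first
    occurrence.  Cleveland-style labels are binarized as
    ``y = 1 if label > threshold else 0``.

    Returns ``(CleanTable, PreprocessReport)``.  Raises if nothing survives;
    flags (not raises) a single-class result.
    """
    report = PreprocessReport()
    kept = []
    for row in raw.rows:
        if any(isinstance(c, str) and c == raw.missing_marker for c in row):
            report.missing_dropped += 1
        else:
            kept.append(row)
    seen = set()
    unique_rows = []
    for row in kept:
        key = tuple(row)
        if key in seen:
            report.duplicates_dropped += 1
        else:
            seen.add(key)
            unique_rows.append(row)
    if not unique_rows:
        raise ValueError("empty after preprocessing")
    arr = np.array(unique_rows, dtype=float)
    X, labels = arr[:, :-1], arr[:, -1]
    y = (labels > label_binarize_threshold).astype(int)
    report.n_kept = len(unique_rows)
    if len(np.unique(y)) < 2:
        report.single_class = True
        report.warnings.append("only one class present after preprocessing")
    return CleanTable(X, y, list(raw.attribute_names)), report


def minmax_normalize(table: CleanTable, stats=None):
    """Map each attribute to [0, 1] via (x - min) / (max - min).

    When ``stats`` (a list of per-attribute ``(min, max)`` pairs, as returned
    by a previous call) is given, that transform is re-applied and the result
    clipped into [0, 1] — used to carry training statistics onto held-out
    data without leakage.  Constant attributes map to 0 with a warning.

    Returns ``(CleanTable, stats)``.
    """
    X = table.X.copy()
    if stats is None:
        stats = [(float(c.min()), float(c.max())) for c in X.T]
    out = np.empty_like(X)
    for j, (lo, hi) in enumerate(stats):
        if hi > lo:
            out[:, j] = (X[:, j] - lo) / (hi - lo)
        else:
            warnings.warn(
                f"attribute {table.attribute_names[j]!r} is constant; normalized to 0"
            )
            out[:, j] = 0.0
    np.clip(out, 0.0, 1.0, out=out)
    return CleanTable(out, table.y, list(table.attribute_names)), stats


def _stratified_train_counts(class_sizes, n_train):
    """Largest-remainder allocation of n_train across classes."""
    exact = {c: n_c * n_train / sum(class_sizes.values()) for c, n_c in class_sizes.items()}
    base = {c: int(np.floor(v)) for c, v in exact.items()}
    short = n_train - sum(base.values())
    # distribute the remainder by descending fractional part, class label as tiebreak
    order = sorted(exact, key=lambda c: (-(exact[c] - base[c]), c))
    for c in order[:short]:
        base[c] += 1
    return base


def train_test_split(table: CleanTable, spec: SplitSpec):
    """Deterministic (seeded) train/test partition of the rows.

    Sizes are ``floor(n * frac)`` train / remainder test.  With
    ``stratified=True`` each class contributes its proportional share of the
    training rows (largest-remainder rounding); if any class has fewer than
    2 members the split falls back to unstratified with a warning.
    """
    n = table.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(np.floor(n * spec.train_fraction))
    rng = np.random.default_rng(spec.seed)

    stratified = spec.stratified
    if stratified:
        counts = {int(c): int((table.y == c).sum()) for c in np.unique(table.y)}
        if any(v < 2 for v in counts.values()):
            warnings.warn("a class has < 2 members; falling back to unstratified split")
            stratified = False

    if stratified:
        per_class = _stratified_train_counts(counts, n_train)
        train_idx, test_idx = [], []
        for c in sorted(counts):
            idx = np.flatnonzero(table.y == c)
            idx = rng.permutation(idx)
            k = per_class[c]
            train_idx.extend(idx[:k])
            test_idx.extend(idx[k:])
        train_idx = np.sort(np.array(train_idx, dtype=int))
        test_idx = np.sort(np.array(test_idx, dtype=int))
    else:
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])

    names = list(table.attribute_names)
    return (
        CleanTable(table.X[train_idx], table.y[train_idx], names),
        CleanTable(table.X[test_idx], table.y[test_idx], names),
    )
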