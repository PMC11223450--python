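"""Synthetic UCI-heart-like tabular data with planted ground truth.

The generator emulates the shape of the small clinical heart-disease
benchmarks: ~13 mixed continuous/ordinal attributes, a binary class, a
planted subset of informative attributes, plus injected missing markers
and exact duplicate rows so the preprocessing rules have something to do.

Attributes are class-conditional Gaussians: informative ones have their
class means separated by ``effect_size`` standard deviations (means at
+/- effect_size / 2), noise ones are standard normal regardless of class.
Three attributes are rendered ordinal by quartile binning, mimicking
cp/slope/thal-style fields.  Everything is deterministic per seed, and the
returned ground-truth record carries the planted attribute set and the
injection counts so recovery tests can score themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import RawTable

__all__ = ["SynthSpec", "GroundTruth", "generate", "null_dataset"]


@dataclass
class SynthSpec:
    n_samples: int = 1000
    n_attributes: int = 13
    informative_idx: tuple = (0, 1, 2, 3, 4)
    effect_size: float = 1.0
    class_balance: float = 0.5
    missing_rate: float = 0.02
    duplicate_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.n_attributes < 1:
            raise ValueError("need at least one sample and one attribute")
        if any(j < 0 or j >= self.n_attributes for j in self.informative_idx):
            raise ValueError("informative_idx must index the attributes")
        if not (0 <= self.missing_rate < 1 and 0 <= self.duplicate_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie in (0, 1)")


@dataclass
class GroundTruth:
    informative_idx: tuple
    n_missing_injected: int
    n_duplicates_injected: int
    effect_size: float
    seed: int
    ordinal_idx: tuple = field(default_factory=tuple)


def generate(spec: SynthSpec):
    """Draw a RawTable from the spec; returns ``(RawTable, GroundTruth)``.

    Row count is ``n_samples + round(n_samples * duplicate_rate)`` (the
    duplicates are verbatim copies, label included, appended after the
    originals); ``round(n_samples * missing_rate)`` distinct original rows
    get one attribute cell replaced by the ``?`` marker.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_attributes
    y = rng.binomial(1, spec.class_balance, size=n)
    X = rng.standard_normal(size=(n, d))
    for j in spec.informative_idx:
        X[:, j] += (y - 0.5) * spec.effect_size

    # render the last min(3, d) attributes ordinal via quartile binning
    ordinal_idx = tuple(range(max(0, d - 3), d))
    for j in ordinal_idx:
        edges = np.quantile(X[:, j], [0.25, 0.5, 0.75])
        X[:, j] = np.searchsorted(edges, X[:, j], side="left").astype(float)

    rows = [[float(v) for v in X[i]] + [float(y[i])] for i in range(n)]

    n_missing = int(round(n * spec.missing_rate))
    if n_missing:
        miss_rows = rng.choice(n, size=n_missing, replace=False)
        for i in miss_rows:
            rows[i][int(rng.integers(d))] = "?"

    n_dup = int(round(n * spec.duplicate_rate))
    for _ in range(n_dup):
        rows.append(list(rows[int(rng.integers(n))]))

    names = [f"attr{j}" for j in range(d)]
    truth = GroundTruth(
        informative_idx=tuple(spec.informative_idx),
        n_missing_injected=n_missing, n_duplicates_injected=n_dup,
        effect_size=spec.effect_size, seed=spec.seed, ordinal_idx=ordinal_idx,
    )
    return RawTable(rows, names, "?"), truth


def null_dataset(n: int, seed: int = 0) -> RawTable:
    """Labels independent of every attribute (effect_size = 0, no injection).

    Useful as a chance-level control: every attribute's symmetric
    uncertainty with the class tends to 0 and any classifier's accuracy to
    the majority-class rate.
    """
    if n < 10:
        raise ValueError("null dataset needs n >= 10")
    table, _ = generate(
        SynthSpec(n_samples=n, effect_size=0.0, missing_rate=0.0,
                  duplicate_rate=0.0, seed=seed)
    )
    return table
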