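"""Model / Results front end for the hybrid CVD classifier.

:class:`HybridCVDModel` is the package's top-level API in the familiar
model-object idiom: construct it from data (a cleaned table, a pandas
DataFrame, a UCI-dialect file, or a synthetic-data spec), call
:meth:`~HybridCVDModel.fit`, and read the returned
:class:`HybridCVDResults` — per-repeat metric reports, selected feature
sets, convergence traces and a multi-run accuracy summary, with a
``summary()`` table and a convergence plot.
"""

from __future__ import annotations

import numpy as np

from .data_io import CleanTable
from .metrics import METRIC_ORDER
from .pipeline import RunConfig, run
from .synthetic_data import SynthSpec

__all__ = ["HybridCVDModel", "HybridCVDResults"]


class HybridCVDModel:
    """Hybrid LSTM + QNN cardiovascular risk classifier.

    Parameters mirror :class:`~cvdhybrid.pipeline.RunConfig`; any keyword
    accepted there can be passed through ``**config``.
    """

    def __init__(self, data=None, *, synth: SynthSpec | None = None,
                 data_path=None, dialect: str = "cleveland", **config):
        if isinstance(data, SynthSpec):
            synth, data = data, None
        self._data = data
        self._synth = synth
        self._data_path = data_path
        self._dialect = dialect
        self._config = config

    @classmethod
    def from_dataframe(cls, df, label_col: str, **config) -> "HybridCVDModel":
        """Build from a pandas DataFrame with a binary label column."""
        X = df.drop(columns=[label_col]).to_numpy(dtype=float)
        y = df[label_col].to_numpy(dtype=int)
        names = [c for c in df.columns if c != label_col]
        return cls(CleanTable(X, y, names), **config)

    @classmethod
    def from_synthetic(cls, spec: SynthSpec | None = None, **config):
        return cls(synth=spec or SynthSpec(), **config)

    def fit(self, n_repeats: int = 5, seed: int = 0) -> "HybridCVDResults":
        """Run the full pipeline ``n_repeats`` times (seeds seed + k)."""
        config = RunConfig(
            synth=self._synth, data_path=self._data_path,
            dialect=self._dialect, n_repeats=n_repeats, base_seed=seed,
            **dict(self._config),
        )
        result = run(config, table=self._data)
        return HybridCVDResults(self, config, result)


class HybridCVDResults:
    """Fitted-run container: estimates, diagnostics and summary table."""

    def __init__(self, model: HybridCVDModel, config: RunConfig,
                 result: RunResult):
        self.model = model
        self.config = config
        self.raw = result
        self.reports = [r.report for r in result.repeats]
        self.selected_features_ = [r.selected_names for r in result.repeats]
        self.convergence_ = [r.fs_history for r in result.repeats]
        self.accuracy_summary = result.summary

    @property
    def accuracies(self) -> np.ndarray:
        return self.raw.accuracies

    def metric_table(self) -> np.ndarray:
        """(n_repeats, 9) array in the reported metric order."""
        return np.array([[getattr(r, m) for m in METRIC_ORDER]
                         for r in self.reports])

    def summary(self) -> str:
        """Plain-text summary: per-repeat metrics + accuracy statistics."""
        lines = ["Hybrid LSTM+QNN CVD classifier — fit summary",
                 "=" * 56]
        header = "repeat  " + "  ".join(f"{m:>11s}" for m in METRIC_ORDER)
        lines.append(header)
        for rep, r in zip(self.raw.repeats, self.reports):
            vals = "  ".join(f"{getattr(r, m):11.4f}" for m in METRIC_ORDER)
            lines.append(f"{rep.seed:6d}  {vals}")
        s = self.accuracy_summary
        lines.append("-" * 56)
        lines.append(
            f"accuracy over {len(self.reports)} repeats:  "
            f"mean={s.mean:.4f}  median={s.median:.4f}  sd={s.sd:.4f}  "
            f"worst={s.worst:.4f}  best={s.best:.4f}"
        )
        sel = self.selected_features_[int(np.argmax(self.accuracies))]
        lines.append(f"selected features (best repeat): {', '.join(sel)}")
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """Best-fitness-vs-iteration traces of the selection runs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for rep, hist in zip(self.raw.repeats, self.convergence_):
            ax.plot(range(1, len(hist) + 1), hist, label=f"seed {rep.seed}")
        ax.set_xlabel("iteration")
        ax.set_ylabel("best selection fitness")
        ax.legend(fontsize="small")
        return ax
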