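"""End-to-end orchestration: clean -> features -> select -> train -> score.

One repeat of :func:`run` executes the four-stage procedure on one seed:

1. load (or synthesize) the raw table and apply the cleaning rules;
2. split train/test, min-max normalize with training statistics only,
   and assemble the four statistical feature families;
3. wrapper feature selection with the SIAO optimizer, scored by a fast
   inner hybrid trained with reduced epochs on an inner validation fold;
4. train the LSTM and the QNN on the selected columns, re-tune the LSTM
   forget gate with SIAO on a validation fold, and score the averaged
   hybrid on the held-out test split.

Repeats use seeds ``base_seed + k``; the accuracy summary reports mean,
median, sample SD (n-1 divisor), worst and best across repeats, matching
the usual multi-run reporting for stochastic optimizers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classifiers import (
    HybridModel, hybrid_predict_proba, init_lstm, init_qnn,
    lstm_train_gd, lstm_tune_siao, qnn_train,
)
from .data_io import (
    CleanTable, SplitSpec, minmax_normalize, preprocess,
    read_statlog, read_uci_cleveland, train_test_split,
)
from .feature_extraction import assemble_features
from .metrics import MetricReport, compute_metrics, confusion
from .siao import SIAOParams, select_features
from .synthetic_data import SynthSpec, generate

__all__ = ["RunConfig", "RunResult", "SummaryStats", "run", "summarize",
           "write_outputs"]


@dataclass
class RunConfig:
    """Everything one multi-repeat experiment needs.

    Exactly one data source: ``synth`` (a SynthSpec, re-seeded per repeat)
    or ``data_path`` + ``dialect`` in {"cleveland", "statlog"}.
    """

    synth: SynthSpec | None = None
    data_path: str | None = None
    dialect: str = "cleveland"
    train_fraction: float = 0.9
    stratified: bool = True
    trim_p: float = 0.1
    winsor_p: float = 0.1
    # wrapper feature selection
    fs_pop: int = 8
    fs_iters: int = 12
    fs_weights: tuple = (0.94, 0.05, 0.01)
    inner_epochs: int = 25
    inner_max_samples: int = 300
    # classifiers
    lstm_hidden: int = 8
    lstm_epochs: int = 200
    lstm_lr: float = 1.0
    qnn_hidden: int = 8
    qnn_n_s: int = 3
    qnn_beta: float = 1.0
    qnn_epochs: int = 250
    qnn_lr: float = 0.5
    # LSTM weight tuning
    tune_pop: int = 6
    tune_iters: int = 10
    tune_scope: str = "forget_gate"
    # repeats
    n_repeats: int = 5
    base_seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class SummaryStats:
    mean: float
    median: float
    sd: float
    worst: float
    best: float


@dataclass
class RepeatResult:
    seed: int
    report: MetricReport
    selected: tuple
    selected_names: tuple
    fs_history: np.ndarray
    tune_history: np.ndarray | None
    model: HybridModel


@dataclass
class RunResult:
    repeats: list
    summary: SummaryStats
    errors: list = field(default_factory=list)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.report.accuracy for r in self.repeats])


def summarize(accuracies) -> SummaryStats:
    """Mean / median / sample SD (n-1) / worst / best of a metric vector."""
    a = np.asarray(accuracies, dtype=float)
    if a.size == 0:
        raise ValueError("nothing to summarize")
    sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
    return SummaryStats(
        mean=float(a.mean()), median=float(np.median(a)), sd=sd,
        worst=float(a.min()), best=float(a.max()),
    )


def _load_clean(config: RunConfig, seed: int) -> CleanTable:
    if config.synth is None and config.data_path is None:
        raise ValueError("no data source: set synth or data_path, "
                         "or pass a table to run()")
    if config.synth is not None:
        spec = SynthSpec(**{**config.synth.__dict__, "seed": seed})
        raw, _ = generate(spec)
    elif config.dialect == "cleveland":
        raw = read_uci_cleveland(config.data_path)
    elif config.dialect == "statlog":
        raw = read_statlog(config.data_path)
    else:
        raise ValueError(f"unknown dialect {config.dialect!r}")
    clean, _ = preprocess(raw)
    return clean


def _train_hybrid(X, y, cols, config: RunConfig, seed: int, epochs_scale=1.0):
    Xs = X[:, cols]
    lstm0 = init_lstm(1, config.lstm_hidden, seed=seed)
    lstm = lstm_train_gd(
        lstm0, Xs, y, epochs=max(1, int(config.lstm_epochs * epochs_scale)),
        lr=config.lstm_lr,
    )
    qnn0 = init_qnn(len(cols), config.qnn_hidden, config.qnn_n_s,
                    config.qnn_beta, seed=seed)
    qnn = qnn_train(
        qnn0, Xs, y, epochs=max(1, int(config.qnn_epochs * epochs_scale)),
        lr=config.qnn_lr,
    )
    return HybridModel(lstm, qnn)


def _run_one(config: RunConfig, seed: int,
             clean: CleanTable | None = None) -> RepeatResult:
    if clean is None:
        clean = _load_clean(config, seed)
    split = SplitSpec(config.train_fraction, seed=seed,
                      stratified=config.stratified)
    train, test = train_test_split(clean, split)
    train_n, stats = minmax_normalize(train)
    test_n, _ = minmax_normalize(test, stats=stats)
    feats = assemble_features(train_n, config.trim_p, config.winsor_p)
    feats_test = assemble_features(test_n, config.trim_p, config.winsor_p)

    # inner fold for the feature-selection fitness: a reduced-epoch hybrid
    rng = np.random.default_rng(seed)
    n_tr = train_n.n_samples
    perm = rng.permutation(n_tr)
    n_val = max(1, n_tr // 5)
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    if fit_idx.size > config.inner_max_samples:
        fit_idx = fit_idx[: config.inner_max_samples]
    Xin, yin = feats.X_aug[fit_idx], feats.y[fit_idx]
    Xval, yval = feats.X_aug[val_idx], feats.y[val_idx]
    scale = config.inner_epochs / max(config.lstm_epochs, 1)

    def eval_subset(cols):
        cols = list(cols)
        inner = _train_hybrid(Xin, yin, cols, config, seed, epochs_scale=scale)
        pred = (hybrid_predict_proba(inner, Xval[:, cols]) >= 0.5).astype(int)
        return float(np.mean(pred != yval))

    fs_res = select_features(
        feats, eval_subset,
        SIAOParams(n_pop=config.fs_pop, n_iter=config.fs_iters, seed=seed),
        weights=config.fs_weights,
    )
    cols = list(fs_res.selected)
    if not cols:
        warnings.warn("feature selection returned an empty set; using all columns")
        cols = list(range(feats.X_aug.shape[1]))

    # final training on the training split, with a validation fold for tuning
    model = _train_hybrid(feats.X_aug, feats.y, cols, config, seed)
    tune_history = None
    if config.tune_iters > 0:
        tuned, tune_res = lstm_tune_siao(
            model.lstm, Xval[:, cols], yval,
            SIAOParams(n_pop=config.tune_pop, n_iter=config.tune_iters,
                       seed=seed),
            scope=config.tune_scope,
        )
        model = HybridModel(tuned, model.qnn)
        tune_history = tune_res.history if tune_res is not None else None

    probs = hybrid_predict_proba(model, feats_test.X_aug[:, cols])
    pred = (probs >= model.threshold).astype(int)
    report = compute_metrics(confusion(test_n.y, pred))
    return RepeatResult(
        seed=seed, report=report, selected=tuple(cols),
        selected_names=tuple(feats.column_names[j] for j in cols),
        fs_history=fs_res.history, tune_history=tune_history, model=model,
    )


def run(config: RunConfig, table: CleanTable | None = None) -> RunResult:
    """Execute ``n_repeats`` independent repeats and summarize accuracy.

    ``table`` bypasses the configured data source with an in-memory
    CleanTable (the split seed still varies per repeat).
    """
    if table is None and config.synth is None and config.data_path is None:
        raise ValueError("no data source: set synth or data_path, "
                         "or pass a table to run()")
    repeats, errors = [], []
    for k in range(config.n_repeats):
        seed = config.base_seed + k
        try:
            repeats.append(_run_one(config, seed, clean=table))
        except Exception as exc:  # noqa: BLE001 - recorded, not silenced
            errors.append((seed, repr(exc)))
    if not repeats:
        raise RuntimeError(f"all repeats failed: {errors}")
    result = RunResult(
        repeats=repeats,
        summary=summarize([r.report.accuracy for r in repeats]),
        errors=errors,
    )
    if config.output_dir is not None:
        write_outputs(result, config.output_dir)
    return result


def write_outputs(result: RunResult, outdir) -> None:
    """metrics.json, summary.csv, convergence.csv, selected_features.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "metrics.json", "w") as fh:
        json.dump(
            [dict(seed=r.seed, **r.report.as_dict()) for r in result.repeats],
            fh, indent=1,
        )
    s = result.summary
    (out / "summary.csv").write_text(
        "Mean,Median,SD,Worst,Best\n"
        f"{s.mean:.6f},{s.median:.6f},{s.sd:.6f},{s.worst:.6f},{s.best:.6f}\n"
    )
    lines = ["repeat,iteration,best_fitness"]
    for r in result.repeats:
        for t, fval in enumerate(r.fs_history, start=1):
            lines.append(f"{r.seed},{t},{fval:.8f}")
    (out / "convergence.csv").write_text("\n".join(lines) + "\n")
    with open(out / "selected_features.json", "w") as fh:
        json.dump(
            [dict(seed=r.seed, columns=list(r.selected),
                  names=list(r.selected_names)) for r in result.repeats],
            fh, indent=1,
        )
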