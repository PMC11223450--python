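"""From-scratch LSTM and quantum neural network, and their hybrid average.

The LSTM is the standard gated recurrence

    f_t = sigma(W_f [h_{t-1}, x_t] + b_f)
    i_t = sigma(W_i [h_{t-1}, x_t] + b_i)
    g_t = tanh (W_c [h_{t-1}, x_t] + b_c)
    C_t = f_t C_{t-1} + i_t g_t
    o_t = sigma(W_o [h_{t-1}, x_t] + b_o)
    h_t = o_t tanh(C_t)

with a sigmoid readout of the final hidden state.  Tabular samples are
presented as univariate sequences: the selected feature values of one
sample, in fixed column order, are the timesteps.  Training is full-batch
gradient descent on cross-entropy with analytic backpropagation through
time; the forget-gate weights can afterwards be re-tuned by the SIAO
optimizer against a validation fold.

The "quantum" network is a classical feedforward net whose hidden units
average n_s shifted sigmoids — a multi-level transfer function

    b_r = (1/n_s) sum_s sigma(beta (W_r x - theta_{r,s}))

whose jump positions theta (the quantum intervals) are learned along with
the weights.  With n_s = 1 and theta = 0 it reduces exactly to an ordinary
one-hidden-layer sigmoid MLP.

The hybrid predictor averages the two probabilities; ties at the decision
threshold go to the positive class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LSTMWeights",
    "QNNParams",
    "HybridModel",
    "init_lstm",
    "lstm_forward",
    "lstm_predict_proba",
    "lstm_loss_and_grads",
    "lstm_train_gd",
    "lstm_tune_siao",
    "init_qnn",
    "qnn_hidden",
    "qnn_forward",
    "qnn_predict_proba",
    "qnn_loss_and_grads",
    "qnn_train",
    "hybrid_predict",
    "hybrid_predict_proba",
]


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class LSTMWeights:
    """Gate matrices (h x (h + input_dim)), biases and sigmoid readout."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray
    w_out: np.ndarray
    b_out: float

    def __post_init__(self):
        h, hd = self.W_f.shape
        for m in (self.W_i, self.W_c, self.W_o):
            if m.shape != (h, hd):
                raise ValueError("gate matrices must share one shape")
        for b in (self.b_f, self.b_i, self.b_c, self.b_o, self.w_out):
            if b.shape != (h,):
                raise ValueError("bias/readout length must equal hidden size")

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]

    def copy(self) -> "LSTMWeights":
        return LSTMWeights(
            self.W_f.copy(), self.W_i.copy(), self.W_c.copy(), self.W_o.copy(),
            self.b_f.copy(), self.b_i.copy(), self.b_c.copy(), self.b_o.copy(),
            self.w_out.copy(), float(self.b_out),
        )

    def to_dict(self) -> dict:
        d = {k: np.asarray(v).tolist() for k, v in self.__dict__.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LSTMWeights":
        arrays = {k: np.array(v) for k, v in d.items() if k != "b_out"}
        return cls(b_out=float(d["b_out"]), **arrays)


def init_lstm(input_dim: int = 1, hidden_size: int = 8, seed=None,
              scale: float = 0.2) -> LSTMWeights:
    """Small random initialization; forget-gate bias starts at 1."""
    rng = np.random.default_rng(seed)
    h, hd = hidden_size, hidden_size + input_dim
    mk = lambda: rng.normal(0.0, scale, size=(h, hd))
    return LSTMWeights(
        W_f=mk(), W_i=mk(), W_c=mk(), W_o=mk(),
        b_f=np.ones(h), b_i=np.zeros(h), b_c=np.zeros(h), b_o=np.zeros(h),
        w_out=rng.normal(0.0, scale, size=h), b_out=0.0,
    )


def _as_batch(sequences, input_dim):
    X = np.asarray(sequences, dtype=float)
    if X.ndim == 1:
        X = X[None, :, None] if input_dim == 1 else X[None, None, :]
    elif X.ndim == 2:
        X = X[:, :, None]  # (B, T) univariate
    return X


def _lstm_run(w: LSTMWeights, X: np.ndarray, cache: bool = False):
    """Batch forward pass. X is (B, T, d); returns probs and optional cache."""
    B, T, d = X.shape
    h = w.hidden_size
    if d != w.input_dim:
        raise ValueError(f"input dim {d} != weight input dim {w.input_dim}")
    ht = np.zeros((B, h))
    ct = np.zeros((B, h))
    steps = []
    for t in range(T):
        z = np.hstack([ht, X[:, t, :]])
        f = _sigmoid(z @ w.W_f.T + w.b_f)
        i = _sigmoid(z @ w.W_i.T + w.b_i)
        g = np.tanh(z @ w.W_c.T + w.b_c)
        o = _sigmoid(z @ w.W_o.T + w.b_o)
        c_prev = ct
        ct = f * c_prev + i * g
        hc = np.tanh(ct)
        ht = o * hc
        if cache:
            steps.append((z, f, i, g, o, c_prev, ct, hc))
    logits = ht @ w.w_out + w.b_out
    probs = _sigmoid(logits)
    return (probs, ht, steps) if cache else (probs, ht, None)


def lstm_forward(weights: LSTMWeights, sequence) -> float:
    """Probability of the positive class for a single sample sequence."""
    X = _as_batch(sequence, weights.input_dim)
    probs, _, _ = _lstm_run(weights, X)
    return float(probs[0])


def lstm_predict_proba(weights: LSTMWeights, sequences) -> np.ndarray:
    """Probabilities for a batch; rows of a 2-D input are univariate sequences."""
    X = _as_batch(sequences, weights.input_dim)
    probs, _, _ = _lstm_run(weights, X)
    return probs


def lstm_loss_and_grads(w: LSTMWeights, sequences, y):
    """Mean cross-entropy and analytic BPTT gradients for all parameters."""
    X = _as_batch(sequences, w.input_dim)
    y = np.asarray(y, dtype=float)
    B, T, _ = X.shape
    h = w.hidden_size
    probs, hT, steps = _lstm_run(w, X, cache=True)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))

    dlogit = (probs - y) / B
    grads = {
        "w_out": hT.T @ dlogit,
        "b_out": float(dlogit.sum()),
        "W_f": np.zeros_like(w.W_f), "W_i": np.zeros_like(w.W_i),
        "W_c": np.zeros_like(w.W_c), "W_o": np.zeros_like(w.W_o),
        "b_f": np.zeros(h), "b_i": np.zeros(h),
        "b_c": np.zeros(h), "b_o": np.zeros(h),
    }
    dh = dlogit[:, None] * w.w_out[None, :]
    dc_next = np.zeros((B, h))
    for t in range(T - 1, -1, -1):
        z, f, i, g, o, c_prev, ct, hc = steps[t]
        do = dh * hc
        dc = dc_next + dh * o * (1.0 - hc**2)
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        dc_next = dc * f
        dzf = df * f * (1.0 - f)
        dzi = di * i * (1.0 - i)
        dzg = dg * (1.0 - g**2)
        dzo = do * o * (1.0 - o)
        grads["W_f"] += dzf.T @ z
        grads["W_i"] += dzi.T @ z
        grads["W_c"] += dzg.T @ z
        grads["W_o"] += dzo.T @ z
        grads["b_f"] += dzf.sum(axis=0)
        grads["b_i"] += dzi.sum(axis=0)
        grads["b_c"] += dzg.sum(axis=0)
        grads["b_o"] += dzo.sum(axis=0)
        dz = dzf @ w.W_f + dzi @ w.W_i + dzg @ w.W_c + dzo @ w.W_o
        dh = dz[:, :h]
    return loss, grads


def _clip_grads(grads, max_norm):
    total = np.sqrt(sum(float(np.sum(np.square(g))) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        grads = {k: g * scale for k, g in grads.items()}
    return grads


def lstm_train_gd(weights: LSTMWeights | None, sequences, y, epochs: int = 200,
                  lr: float = 1.0, seed=None, clip: float = 5.0) -> LSTMWeights:
    """Full-batch gradient descent on cross-entropy.

    When ``weights`` is None a fresh network is initialized from ``seed``
    (with input_dim taken from the data); otherwise the given weights are
    the starting point and seed only matters for that fresh path, so the
    whole procedure is deterministic.  Gradients are clipped to global norm
    ``clip``.  Raises if the loss turns non-finite (lower the learning
    rate).
    """
    if lr < 0:
        raise ValueError("learning rate must be >= 0")
    if weights is None:
        weights = init_lstm(input_dim=1, hidden_size=8, seed=seed)
    w = weights.copy()
    if lr == 0 or epochs == 0:
        return w
    for _ in range(epochs):
        loss, grads = lstm_loss_and_grads(w, sequences, y)
        if not np.isfinite(loss):
            raise FloatingPointError(
                "training diverged (non-finite loss); lower the learning rate"
            )
        grads = _clip_grads(grads, clip)
        for k, g in grads.items():
            setattr(w, k, getattr(w, k) - lr * g)
    return w


_SCOPES = {
    "forget_gate": ("W_f", "b_f"),
    "all_gates": ("W_f", "W_i", "W_c", "W_o", "b_f", "b_i", "b_c", "b_o"),
}


def lstm_tune_siao(weights: LSTMWeights, sequences, y, siao_params,
                   scope: str = "forget_gate", bound: float = 2.0,
                   jitter: float = 0.05):
    """Re-tune scoped LSTM weights with SIAO against validation error.

    The scoped parameters (default: the forget gate, W_f and b_f) are
    flattened into the search vector; the population starts at the trained
    values, one member exactly there and the rest normally jittered, inside
    bounds [-B, B] widened if needed to contain the trained values.
    Fitness is the misclassification error on the given validation fold, so
    greedy elitism guarantees the returned weights are no worse there.

    Returns ``(tuned_weights, OptimizeResult)``.
    """
    from .siao import SIAOParams, optimize

    if scope not in _SCOPES:
        raise ValueError(f"scope must be one of {sorted(_SCOPES)}")
    y = np.asarray(y, dtype=int)
    if y.size == 0:
        raise ValueError("validation fold is empty")
    names = _SCOPES[scope]
    shapes = [getattr(weights, nm).shape for nm in names]
    sizes = [int(np.prod(s)) for s in shapes]
    x_trained = np.concatenate([getattr(weights, nm).ravel() for nm in names])
    b = max(bound, 1.05 * float(np.max(np.abs(x_trained))) + 1e-9)

    def inject(vec):
        w = weights.copy()
        off = 0
        for nm, shp, sz in zip(names, shapes, sizes):
            setattr(w, nm, vec[off:off + sz].reshape(shp))
            off += sz
        return w

    def fitness(vec):
        w = inject(vec)
        pred = (lstm_predict_proba(w, sequences) >= 0.5).astype(int)
        return float(np.mean(pred != y))

    params = SIAOParams(
        **{**siao_params.__dict__, "dim": x_trained.size, "lb": -b, "ub": b}
    )
    if params.n_iter == 0:  # no-op bound
        return weights.copy(), None
    rng = np.random.default_rng(params.seed)
    x0 = np.tile(x_trained, (params.n_pop, 1))
    x0[1:] += rng.normal(0.0, jitter, size=(params.n_pop - 1, x_trained.size))
    res = optimize(fitness, params, x0=x0)
    return inject(res.x_best), res


@dataclass
class QNNParams:
    """Multi-level-sigmoid network parameters; theta rows sorted ascending."""

    W: np.ndarray          # (n_hidden, input_dim)
    theta: np.ndarray      # (n_hidden, n_s)
    beta: float
    v: np.ndarray          # output weights (n_hidden,)
    b_out: float

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("slope factor beta must be positive")
        if self.theta.ndim != 2 or self.theta.shape[0] != self.W.shape[0]:
            raise ValueError("theta must be (n_hidden, n_s)")
        self.theta = np.sort(self.theta, axis=1)

    @property
    def n_s(self) -> int:
        return self.theta.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "QNNParams":
        return QNNParams(self.W.copy(), self.theta.copy(), float(self.beta),
                         self.v.copy(), float(self.b_out))

    def to_dict(self) -> dict:
        return {
            "W": self.W.tolist(), "theta": self.theta.tolist(),
            "beta": self.beta, "v": self.v.tolist(), "b_out": self.b_out,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QNNParams":
        return cls(np.array(d["W"]), np.array(d["theta"]), float(d["beta"]),
                   np.array(d["v"]), float(d["b_out"]))


def init_qnn(input_dim: int, n_hidden: int = 8, n_s: int = 3,
             beta: float = 1.0, seed=None, scale: float = 0.5) -> QNNParams:
    """Random weights; quantum intervals start as jittered, sorted grid."""
    rng = np.random.default_rng(seed)
    theta = np.linspace(-1.0, 1.0, n_s)[None, :] + rng.normal(
        0.0, 0.1, size=(n_hidden, n_s)
    )
    return QNNParams(
        W=rng.normal(0.0, scale, size=(n_hidden, input_dim)),
        theta=np.sort(theta, axis=1), beta=beta,
        v=rng.normal(0.0, scale, size=n_hidden), b_out=0.0,
    )


def _qnn_hidden_batch(p: QNNParams, X: np.ndarray):
    """X (B, d) -> activations (B, n_hidden) and per-level sigmoids."""
    a = X @ p.W.T                                   # (B, m)
    s = _sigmoid(p.beta * (a[:, :, None] - p.theta[None, :, :]))  # (B, m, n_s)
    return s.mean(axis=2), s, a


def qnn_hidden(params: QNNParams, x) -> np.ndarray:
    """Hidden activation b_r = (1/n_s) sum_s sigmoid(beta (W_r x - theta_rs))."""
    x = np.asarray(x, dtype=float).reshape(1, -1)
    b, _, _ = _qnn_hidden_batch(params, x)
    return b[0]


def qnn_forward(params: QNNParams, x) -> float:
    """Positive-class probability for one input vector."""
    b = qnn_hidden(params, x)
    return float(_sigmoid(b @ params.v + params.b_out))


def qnn_predict_proba(params: QNNParams, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    b, _, _ = _qnn_hidden_batch(params, X)
    return _sigmoid(b @ params.v + params.b_out)


def qnn_loss_and_grads(p: QNNParams, X, y):
    """Mean cross-entropy and analytic gradients for W, theta, v, b_out."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    B = X.shape[0]
    b, s, _ = _qnn_hidden_batch(p, X)
    probs = _sigmoid(b @ p.v + p.b_out)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))

    dlogit = (probs - y) / B                        # (B,)
    grads = {
        "v": b.T @ dlogit,
        "b_out": float(dlogit.sum()),
    }
    db = dlogit[:, None] * p.v[None, :]             # (B, m)
    sprime = s * (1.0 - s)                          # (B, m, n_s)
    da = db * (p.beta / p.n_s) * sprime.sum(axis=2)  # (B, m)
    grads["W"] = da.T @ X
    grads["theta"] = -(p.beta / p.n_s) * np.einsum("bm,bms->ms", db, sprime)
    return loss, grads


def qnn_train(params: QNNParams | None, X, y, epochs: int = 200,
              lr: float = 0.5, seed=None, clip: float = 5.0) -> QNNParams:
    """Full-batch gradient descent on cross-entropy, training W, theta, v.

    Theta rows are re-sorted ascending after every update to preserve the
    quantum-interval ordering invariant.  Deterministic given ``seed``
    (only used to initialize when ``params`` is None).
    """
    if lr < 0:
        raise ValueError("learning rate must be >= 0")
    if params is None:
        params = init_qnn(np.asarray(X).shape[1], seed=seed)
    p = params.copy()
    if lr == 0 or epochs == 0:
        return p
    for _ in range(epochs):
        loss, grads = qnn_loss_and_grads(p, X, y)
        if not np.isfinite(loss):
            raise FloatingPointError(
                "training diverged (non-finite loss); lower the learning rate"
            )
        grads = _clip_grads(grads, clip)
        p.W -= lr * grads["W"]
        p.theta -= lr * grads["theta"]
        p.v -= lr * grads["v"]
        p.b_out -= lr * grads["b_out"]
        p.theta = np.sort(p.theta, axis=1)
    return p


@dataclass
class HybridModel:
    """Soft-voting average of a trained LSTM and a trained QNN."""

    lstm: LSTMWeights
    qnn: QNNParams
    threshold: float = 0.5

    def __post_init__(self):
        if self.qnn.input_dim < 1:
            raise ValueError("QNN input dimension must be positive")

    def save_json(self, path):
        with open(path, "w") as fh:
            json.dump(
                {"lstm": self.lstm.to_dict(), "qnn": self.qnn.to_dict(),
                 "threshold": self.threshold}, fh)

    @classmethod
    def load_json(cls, path) -> "HybridModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(LSTMWeights.from_dict(d["lstm"]),
                   QNNParams.from_dict(d["qnn"]), float(d["threshold"]))


def hybrid_predict(model: HybridModel, x):
    """(probability, label) for one sample's feature vector.

    probability = (p_LSTM + p_QNN) / 2; label = 1 iff probability >= the
    decision threshold (ties go positive).
    """
    x = np.asarray(x, dtype=float).ravel()
    p_lstm = lstm_forward(model.lstm, x)
    p_qnn = qnn_forward(model.qnn, x)
    prob = 0.5 * (p_lstm + p_qnn)
    return prob, int(prob >= model.threshold)


def hybrid_predict_proba(model: HybridModel, X) -> np.ndarray:
    """Averaged probabilities for a batch of feature vectors (rows)."""
    X = np.asarray(X, dtype=float)
    return 0.5 * (lstm_predict_proba(model.lstm, X) + qnn_predict_proba(model.qnn, X))
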