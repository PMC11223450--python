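"""Aquila Optimization and its Self-Improved variant (SIAO).

Aquila Optimization (AO) is a population metaheuristic whose four update
rules mimic an eagle's hunting repertoire: a high soar covering the whole
search space (expanded exploration), a contour flight with short glide
attacks driven by Levy steps along a spiral (narrowed exploration), a low
descent over the located prey region (expanded exploitation), and a
walk-and-grab pursuit (narrowed exploitation).  The first two rules fire
while t <= (2/3) T, the last two afterwards, each pair split 50/50 at
random.  Acceptance is greedy against both the individual's current
position and the global best, so the best-so-far trace is non-increasing.

The Self-Improved variant (SIAO) changes the expanded-exploitation phase in
two ways: the uniform random number feeding the descent step is replaced by
a chaotic logistic-map iterate scaled into the bounds, and each accepted
descent step is followed by an arithmetic crossover of two random
population members whose offspring greedily replace their parents.

A binary wrapper (:func:`select_features`) searches the unit hypercube and
thresholds positions at 0.5 to score column subsets for feature selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SIAOParams",
    "SIAOState",
    "OptimizeResult",
    "FeatureSelectionResult",
    "levy_sigma",
    "levy_flight",
    "spiral_terms",
    "logistic_rand",
    "step_expanded_exploration",
    "step_narrowed_exploration",
    "step_expanded_exploitation",
    "step_narrowed_exploitation",
    "optimize",
    "select_features",
]


@dataclass
class SIAOParams:
    """Optimizer configuration.

    alpha/delta are the exploitation adjustment factors (both 0.1), omega
    the spiral angle rate (0.005), r1 the search-cycle radius drawn from
    [1, 20], and the Levy step uses the Mantegna scheme with stability
    index ``levy_k`` = 1.5 and scale ``levy_s`` = 0.01.  ``self_improved``
    switches between baseline AO (uniform exploitation noise, no
    crossover) and SIAO (logistic-map chaos + arithmetic crossover).
    """

    n_pop: int = 20
    n_iter: int = 100
    dim: int = 1
    lb: float | np.ndarray = 0.0
    ub: float | np.ndarray = 1.0
    alpha: float = 0.1
    delta: float = 0.1
    omega: float = 0.005
    r1_range: tuple = (1, 20)
    levy_k: float = 1.5
    levy_s: float = 0.01
    logistic_mu: float = 4.0
    seed: int | None = None
    self_improved: bool = True

    def __post_init__(self):
        if self.n_pop < 2:
            raise ValueError("population size must be >= 2")
        if self.n_iter < 0:
            raise ValueError("iteration count must be non-negative")
        if not 1.0 < self.levy_k <= 2.0:
            raise ValueError("levy_k must lie in (1, 2]")
        self.lb = np.broadcast_to(np.asarray(self.lb, dtype=float), (self.dim,)).copy()
        self.ub = np.broadcast_to(np.asarray(self.ub, dtype=float), (self.dim,)).copy()
        if np.any(self.lb >= self.ub):
            raise ValueError("lower bounds must be strictly below upper bounds")


@dataclass
class SIAOState:
    """Mutable optimizer state threaded through the phase steps."""

    params: SIAOParams
    positions: np.ndarray
    fitness: np.ndarray
    x_best: np.ndarray
    f_best: float
    x_mean: np.ndarray
    t: int
    rng: np.random.Generator
    chaos_state: float
    history: list = field(default_factory=list)
    n_rejected_nonfinite: int = 0


@dataclass
class OptimizeResult:
    x_best: np.ndarray
    f_best: float
    history: np.ndarray
    n_evaluations: int
    n_rejected_nonfinite: int


@dataclass
class FeatureSelectionResult:
    selected: tuple
    fitness: float
    history: np.ndarray
    n_evaluations: int


def levy_sigma(k: float) -> float:
    """Mantegna scale sigma_u for stability index k in (1, 2]."""
    num = math.gamma(1.0 + k) * math.sin(math.pi * k / 2.0)
    den = math.gamma((1.0 + k) / 2.0) * k * 2.0 ** ((k - 1.0) / 2.0)
    return (num / den) ** (1.0 / k)


def levy_flight(dim: int, k: float = 1.5, s: float = 0.01, rng=None) -> np.ndarray:
    """Heavy-tailed Levy step: s * u * sigma / |v|^(1/k), u, v ~ N(0, 1).

    ``v`` entries with magnitude below 1e-12 are resampled to keep the
    ratio finite.
    """
    if not hasattr(rng, "standard_normal"):
        rng = np.random.default_rng(rng)
    sigma = levy_sigma(k)
    u = rng.standard_normal(dim)
    v = rng.standard_normal(dim)
    for _ in range(100):
        tiny = np.abs(v) < 1e-12
        if not tiny.any():
            break
        v[tiny] = rng.standard_normal(int(tiny.sum()))
    return s * u * sigma / np.abs(v) ** (1.0 / k)


def spiral_terms(dim: int, omega: float = 0.005, r1: float = 10.0):
    """Spiral coordinates (x, y) over dimension index D1 = 1..dim.

    r = r1 + 0.00565 D1, phi = -omega D1 + 3 pi / 2;
    x = r sin phi, y = r cos phi.
    """
    d1 = np.arange(1, dim + 1, dtype=float)
    r = r1 + 0.00565 * d1
    phi = -omega * d1 + 1.5 * math.pi
    return r * np.sin(phi), r * np.cos(phi)


def logistic_rand(state: float, mu: float = 4.0, rng=None):
    """One logistic-map iterate: value = mu * state * (1 - state).

    Returns ``(value, new_state)`` with ``new_state = value``.  States at or
    outside (0, 1), or at the map's fixed points {0, 1 - 1/mu}, are reseeded
    from ``rng`` with a warning (the orbit would otherwise freeze).
    """
    fixed = {0.0, 1.0 - 1.0 / mu} if mu != 0 else {0.0}
    if not 0.0 < state < 1.0 or any(abs(state - f) < 1e-12 for f in fixed):
        warnings.warn("logistic-map state at a fixed point; reseeding")
        rng = np.random.default_rng(rng)
        state = float(rng.uniform(0.05, 0.95))
    value = mu * state * (1.0 - state)
    value = float(min(max(value, 0.0), 1.0))
    return value, value


def _clamp(x: np.ndarray, p: SIAOParams) -> np.ndarray:
    return np.clip(x, p.lb, p.ub)


def step_expanded_exploration(state: SIAOState, i: int) -> np.ndarray:
    """High-soar update: X1 = X_best (1 - t/T) + (X_M - X_best * rand)."""
    p = state.params
    rand = state.rng.uniform(size=p.dim)
    x1 = state.x_best * (1.0 - state.t / p.n_iter) + (
        state.x_mean - state.x_best * rand
    )
    return _clamp(x1, p)


def step_narrowed_exploration(state: SIAOState, i: int) -> np.ndarray:
    """Contour-flight update: X2 = X_best * LF(D) + X_R + (y - x) rand.

    X_R is a uniformly chosen population member distinct from i.
    """
    p = state.params
    if p.n_pop < 2:
        raise ValueError("narrowed exploration needs at least 2 individuals")
    j = int(state.rng.integers(p.n_pop - 1))
    if j >= i:
        j += 1
    lf = levy_flight(p.dim, p.levy_k, p.levy_s, state.rng)
    r1 = float(state.rng.integers(p.r1_range[0], p.r1_range[1] + 1))
    x_sp, y_sp = spiral_terms(p.dim, p.omega, r1)
    rand = state.rng.uniform(size=p.dim)
    x2 = state.x_best * lf + state.positions[j] + (y_sp - x_sp) * rand
    return _clamp(x2, p)


def step_expanded_exploitation(state: SIAOState, i: int) -> np.ndarray:
    """Low-descent update:
    X3 = (X_best - X_M) alpha - rand + ((UB - LB) r + LB) delta.

    In SIAO the scalar r is a logistic-map chaotic iterate; baseline AO
    draws it uniformly.
    """
    p = state.params
    rand = state.rng.uniform(size=p.dim)
    if p.self_improved:
        r, state.chaos_state = logistic_rand(
            state.chaos_state, p.logistic_mu, state.rng
        )
    else:
        r = float(state.rng.uniform())
    x3 = (state.x_best - state.x_mean) * p.alpha - rand + (
        (p.ub - p.lb) * r + p.lb
    ) * p.delta
    return _clamp(x3, p)


def step_narrowed_exploitation(state: SIAOState, i: int) -> np.ndarray:
    """Walk-and-grab update:
    X4 = QF X_best - (G1 X(t) rand) - G2 LF(D) + rand G1,
    QF = t^((2 rand - 1)/(1 - T)^2), G1 = 2 rand - 1, G2 = 2 (1 - t/T).
    QF and G1 are scalars per candidate; the remaining rand draws are fresh
    per use and per dimension.
    """
    p = state.params
    rng = state.rng
    t, T = state.t, p.n_iter
    qf = float(t ** ((2.0 * rng.uniform() - 1.0) / (1.0 - T) ** 2)) if T > 1 else 1.0
    g1 = 2.0 * rng.uniform() - 1.0
    g2 = 2.0 * (1.0 - t / T)
    lf = levy_flight(p.dim, p.levy_k, p.levy_s, rng)
    rand1 = rng.uniform(size=p.dim)
    rand2 = rng.uniform(size=p.dim)
    x4 = qf * state.x_best - (g1 * state.positions[i] * rand1) - g2 * lf + rand2 * g1
    return _clamp(x4, p)


def _safe_eval(fitness, x, state: SIAOState) -> float:
    try:
        f = float(fitness(x))
    except Exception:
        state.n_rejected_nonfinite += 1
        return math.inf
    if not math.isfinite(f):
        state.n_rejected_nonfinite += 1
        return math.inf
    return f


def _crossover(state: SIAOState, fitness) -> int:
    """Arithmetic crossover of two random parents with greedy replacement."""
    p = state.params
    if p.n_pop < 2:
        warnings.warn("population too small for crossover; skipped")
        return 0
    a, b = state.rng.choice(p.n_pop, size=2, replace=False)
    lam = float(state.rng.uniform())
    o1 = lam * state.positions[a] + (1.0 - lam) * state.positions[b]
    o2 = (1.0 - lam) * state.positions[a] + lam * state.positions[b]
    n_eval = 0
    for parent, child in ((a, o1), (b, o2)):
        child = _clamp(child, p)
        f = _safe_eval(fitness, child, state)
        n_eval += 1
        if f < state.fitness[parent]:
            state.positions[parent] = child
            state.fitness[parent] = f
            if f < state.f_best:
                state.f_best = f
                state.x_best = child.copy()
    return n_eval


def optimize(fitness, params: SIAOParams, x0: np.ndarray | None = None,
             phase_hook=None) -> OptimizeResult:
    """Run the (SI)AO loop and return the best solution found.

    ``fitness`` maps a D-vector to a scalar to be minimized; candidates with
    non-finite fitness are rejected (counted in the result).  ``x0``
    optionally seeds the initial population (n_pop x dim, clamped to the
    bounds) — used e.g. to start weight tuning at trained values.
    ``phase_hook(phase, i, t)`` is called before each candidate evaluation
    with phase in {"X1", "X2", "X3", "X4"} (instrumentation only).

    The history has length ``n_iter`` and records the best-so-far fitness
    at the end of each iteration; greedy elitism makes it non-increasing.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    if x0 is not None:
        positions = _clamp(np.array(x0, dtype=float).reshape(p.n_pop, p.dim), p)
    else:
        positions = rng.uniform(p.lb, p.ub, size=(p.n_pop, p.dim))

    state = SIAOState(
        params=p, positions=positions,
        fitness=np.empty(p.n_pop), x_best=positions[0].copy(),
        f_best=math.inf, x_mean=positions.mean(axis=0), t=0, rng=rng,
        chaos_state=float(rng.uniform(0.05, 0.95)),
    )
    n_eval = 0
    for i in range(p.n_pop):
        state.fitness[i] = _safe_eval(fitness, positions[i], state)
        n_eval += 1
    best = int(np.argmin(state.fitness))
    state.f_best = float(state.fitness[best])
    state.x_best = positions[best].copy()

    explore_cutoff = (2.0 / 3.0) * p.n_iter
    for t in range(1, p.n_iter + 1):
        state.t = t
        state.x_mean = state.positions.mean(axis=0)
        for i in range(p.n_pop):
            if t <= explore_cutoff:
                if rng.uniform() <= 0.5:
                    phase = "X1"
                    cand = step_expanded_exploration(state, i)
                else:
                    phase = "X2"
                    cand = step_narrowed_exploration(state, i)
            else:
                if rng.uniform() <= 0.5:
                    phase = "X3"
                    cand = step_expanded_exploitation(state, i)
                else:
                    phase = "X4"
                    cand = step_narrowed_exploitation(state, i)
            if phase_hook is not None:
                phase_hook(phase, i, t)
            f = _safe_eval(fitness, cand, state)
            n_eval += 1
            if f < state.fitness[i]:
                state.positions[i] = cand
                state.fitness[i] = f
            if f < state.f_best:
                state.f_best = f
                state.x_best = cand.copy()
            if phase == "X3" and p.self_improved:
                n_eval += _crossover(state, fitness)
        state.history.append(state.f_best)

    return OptimizeResult(
        x_best=state.x_best, f_best=state.f_best,
        history=np.asarray(state.history), n_evaluations=n_eval,
        n_rejected_nonfinite=state.n_rejected_nonfinite,
    )


def select_features(
    feature_set,
    eval_fn,
    params: SIAOParams,
    su_scores: np.ndarray | None = None,
    weights: tuple = (0.94, 0.05, 0.01),
) -> FeatureSelectionResult:
    """Wrapper feature selection over column subsets.

    ``feature_set`` is either a :class:`~cvdhybrid.feature_extraction.FeatureSet`
    (its full-matrix SU vector supplies the relevance term) or an integer
    column count.  Continuous positions in [0, 1]^n_columns are thresholded
    at 0.5 (position > 0.5 selects the column) and scored as

        w_err * eval_fn(subset) + w_card * |subset| / n_columns
            - w_su * mean SU(subset)

    with ``eval_fn`` returning a classification error in [0, 1].  The empty
    subset is assigned fitness 1.  Returns the best subset (sorted column
    indices), its fitness and the convergence trace.
    """
    if hasattr(feature_set, "X_aug"):
        n_columns = feature_set.X_aug.shape[1]
        if su_scores is None:
            su_scores = feature_set.su_all
    else:
        n_columns = int(feature_set)
    if su_scores is None:
        su_scores = np.zeros(n_columns)
    su_scores = np.asarray(su_scores, dtype=float)
    if su_scores.shape != (n_columns,):
        raise ValueError("su_scores length must equal the column count")
    w_err, w_card, w_su = weights

    params = SIAOParams(
        **{**params.__dict__, "dim": n_columns, "lb": 0.0, "ub": 1.0}
    )

    def fitness(pos):
        subset = tuple(int(j) for j in np.flatnonzero(pos > 0.5))
        if not subset:
            return 1.0
        err = float(eval_fn(subset))
        return (
            w_err * err
            + w_card * len(subset) / n_columns
            - w_su * float(su_scores[list(subset)].mean())
        )

    res = optimize(fitness, params)
    selected = tuple(int(j) for j in np.flatnonzero(res.x_best > 0.5))
    return FeatureSelectionResult(
        selected=selected, fitness=res.f_best, history=res.history,
        n_evaluations=res.n_evaluations,
    )
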