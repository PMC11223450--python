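import math

import numpy as np
import pytest

from cvdhybrid.siao import (
    SIAOParams, SIAOState, levy_flight, levy_sigma, logistic_rand,
    optimize, select_features, spiral_terms, step_expanded_exploration,
    step_narrowed_exploration, _crossover,
)


class StubRNG:
    """Deterministic stand-in for a Generator with scripted draws."""

    def __init__(self, uniform=0.0, normal=1.0, integer=0, choice_pair=(0, 1)):
        self._u, self._n, self._i = uniform, normal, integer
        self._pair = choice_pair

    def uniform(self, low=0.0, high=1.0, size=None):
        val = low + self._u * (high - low)
        return np.full(size, val) if size is not None else val

    def standard_normal(self, size=None):
        return np.full(size, self._n) if size is not None else self._n

    def integers(self, low, high=None, size=None):
        return self._i

    def choice(self, n, size=None, replace=True):
        return np.array(self._pair[:size])


def _make_state(params, positions, t=1, rng=None):
    fitness = np.array([float(np.sum(p**2)) for p in positions])
    best = int(np.argmin(fitness))
    return SIAOState(
        params=params, positions=positions.copy(), fitness=fitness,
        x_best=positions[best].copy(), f_best=float(fitness[best]),
        x_mean=positions.mean(axis=0), t=t,
        rng=rng or np.random.default_rng(0), chaos_state=0.3,
    )


class TestLevyFlight:
    def test_sigma_against_gamma_oracle(self):
        # independent evaluation of the Mantegna sigma via sympy's Gamma
        import sympy

        k = sympy.Rational(3, 2)
        expr = (
            (sympy.gamma(1 + k) * sympy.sin(sympy.pi * k / 2))
            / (sympy.gamma((1 + k) / 2) * k * 2 ** ((k - 1) / 2))
        ) ** (1 / k)
        assert levy_sigma(1.5) == pytest.approx(float(expr.evalf(20)), abs=1e-9)

    def test_zero_scale_gives_zero_vector(self):
        assert np.all(levy_flight(6, s=0.0, rng=1) == 0.0)

    def test_seeded_determinism(self):
        a = levy_flight(5, rng=np.random.default_rng(42))
        b = levy_flight(5, rng=np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_invalid_stability_index_rejected(self):
        with pytest.raises(ValueError):
            SIAOParams(dim=2, levy_k=2.5)


class TestSpiral:
    def test_radius_squared_identity(self):
        x, y = spiral_terms(30, omega=0.005, r1=7.0)
        d1 = np.arange(1, 31)
        r = 7.0 + 0.00565 * d1
        np.testing.assert_allclose(x**2 + y**2, r**2)

    def test_zero_omega_linear_radius_on_sin_axis(self):
        x, y = spiral_terms(10, omega=0.0, r1=3.0)
        # phi = 3pi/2 for every D1: sin = -1, cos = 0
        d1 = np.arange(1, 11)
        np.testing.assert_allclose(x, -(3.0 + 0.00565 * d1))
        np.testing.assert_allclose(y, np.zeros(10), atol=1e-12)


class TestLogisticMap:
    def test_single_iterate(self):
        val, new = logistic_rand(0.2, mu=4.0)
        assert val == pytest.approx(0.64)
        assert new == val

    def test_bound_scaling_as_random_number(self):
        val, _ = logistic_rand(0.2, mu=4.0)
        assert 0.0 + val * (10.0 - 0.0) == pytest.approx(6.4)

    def test_orbit_stays_in_unit_interval(self):
        s = 0.3
        for _ in range(10_000):
            v, s = logistic_rand(s, mu=4.0, rng=0)
            assert 0.0 <= v <= 1.0

    def test_fixed_point_reseeded_with_warning(self):
        with pytest.warns(UserWarning, match="fixed point"):
            v, s = logistic_rand(0.75, mu=4.0, rng=3)
        assert 0.0 <= v <= 1.0


class TestPhaseSteps:
    def _params(self, **kw):
        kw.setdefault("n_pop", 4)
        kw.setdefault("n_iter", 10)
        kw.setdefault("dim", 3)
        kw.setdefault("lb", -10.0)
        kw.setdefault("ub", 10.0)
        return SIAOParams(**kw)

    def test_expanded_exploration_rand_one_gives_population_mean(self):
        p = self._params()
        rng = np.random.default_rng(1)
        pos = rng.uniform(-1, 1, size=(4, 3))
        st = _make_state(p, pos, t=0, rng=StubRNG(uniform=1.0))
        cand = step_expanded_exploration(st, 0)
        # X1 = X_best (1 - 0/T) + (X_M - X_best * 1) = X_M
        np.testing.assert_allclose(cand, st.x_mean)

    def test_expanded_exploration_formula_oracle(self):
        p = self._params()
        pos = np.random.default_rng(2).uniform(-1, 1, size=(4, 3))
        seed_rng = np.random.default_rng(77)
        st = _make_state(p, pos, t=4, rng=seed_rng)
        cand = step_expanded_exploration(st, 1)
        rand = np.random.default_rng(77).uniform(size=3)
        expected = st.x_best * (1 - 4 / 10) + (st.x_mean - st.x_best * rand)
        np.testing.assert_allclose(cand, np.clip(expected, -10, 10))

    def test_narrowed_exploration_degenerates_to_neighbour(self):
        # zero Levy scale and rand = 0 leave only the X_R term
        p = self._params(levy_s=0.0)
        pos = np.random.default_rng(3).uniform(-1, 1, size=(4, 3))
        st = _make_state(p, pos, t=2, rng=StubRNG(uniform=0.0, integer=0))
        cand = step_narrowed_exploration(st, 1)  # j=0 (stub), j != i
        np.testing.assert_allclose(cand, pos[0])

    def test_crossover_midpoint_and_identity(self):
        p = self._params()
        pos = np.random.default_rng(4).uniform(-1, 1, size=(4, 3))
        # lam = 0.5: both offspring are the parent midpoint
        st = _make_state(p, pos, rng=StubRNG(uniform=0.5, choice_pair=(0, 1)))
        mid = 0.5 * (pos[0] + pos[1])
        _crossover(st, lambda x: -1.0)  # offspring always accepted
        np.testing.assert_allclose(st.positions[0], mid)
        np.testing.assert_allclose(st.positions[1], mid)
        # lam = 0: offspring are the swapped parents
        st2 = _make_state(p, pos, rng=StubRNG(uniform=0.0, choice_pair=(0, 1)))
        _crossover(st2, lambda x: -1.0)
        np.testing.assert_allclose(st2.positions[0], pos[1])
        np.testing.assert_allclose(st2.positions[1], pos[0])

    def test_crossover_offspring_in_parent_box(self):
        p = self._params()
        rng = np.random.default_rng(5)
        pos = rng.uniform(-1, 1, size=(4, 3))
        st = _make_state(p, pos, rng=np.random.default_rng(6))
        parents = pos.copy()
        _crossover(st, lambda x: -np.random.default_rng(0).uniform())
        for row in st.positions:
            lo = parents.min(axis=0) - 1e-12
            hi = parents.max(axis=0) + 1e-12
            assert np.all(row >= lo) and np.all(row <= hi)


class TestOptimize:
    def test_constant_fitness_flat_history(self):
        p = SIAOParams(n_pop=5, n_iter=20, dim=2, lb=-1, ub=1, seed=0)
        res = optimize(lambda x: 3.25, p)
        assert res.f_best == 3.25
        assert np.all(res.history == 3.25)
        assert len(res.history) == 20

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_history_monotone_nonincreasing(self, seed):
        p = SIAOParams(n_pop=8, n_iter=40, dim=4, lb=-5, ub=5, seed=seed)
        res = optimize(lambda x: float(np.sum(x**2)), p)
        assert np.all(np.diff(res.history) <= 0)

    def test_best_within_bounds(self):
        p = SIAOParams(n_pop=6, n_iter=30, dim=3, lb=-2, ub=3, seed=1)
        res = optimize(lambda x: float(np.sum((x - 10) ** 2)), p)
        assert np.all(res.x_best >= -2) and np.all(res.x_best <= 3)

    def test_nonfinite_fitness_rejected_and_counted(self):
        p = SIAOParams(n_pop=4, n_iter=10, dim=2, lb=-1, ub=1, seed=2)
        calls = {"n": 0}

        def f(x):
            calls["n"] += 1
            return math.nan if calls["n"] % 3 == 0 else float(np.sum(x**2))

        res = optimize(f, p)
        assert res.n_rejected_nonfinite > 0
        assert math.isfinite(res.f_best)

    def test_phase_schedule_respects_two_thirds_cutoff(self):
        p = SIAOParams(n_pop=4, n_iter=9, dim=2, lb=-1, ub=1, seed=3)
        seen = []
        optimize(lambda x: float(np.sum(x**2)), p,
                 phase_hook=lambda ph, i, t: seen.append((t, ph)))
        cutoff = 2 / 3 * 9
        for t, ph in seen:
            if t <= cutoff:
                assert ph in ("X1", "X2")
            else:
                assert ph in ("X3", "X4")

    def test_baseline_ao_matches_siao_during_exploration(self):
        # the self-improved ingredients (chaos + crossover) live in the
        # X3 phase, which cannot fire before t > 2T/3: on shared seeds the
        # two variants produce identical best-so-far traces until then
        f = lambda x: float(np.sum(x**2))
        T = 9
        res_a = optimize(f, SIAOParams(n_pop=6, n_iter=T, dim=3, lb=-4, ub=4,
                                       seed=9, self_improved=True))
        res_b = optimize(f, SIAOParams(n_pop=6, n_iter=T, dim=3, lb=-4, ub=4,
                                       seed=9, self_improved=False))
        cutoff = int(2 * T / 3)
        np.testing.assert_array_equal(res_a.history[:cutoff],
                                      res_b.history[:cutoff])

    def test_seeded_population_start(self):
        p = SIAOParams(n_pop=3, n_iter=1, dim=2, lb=-1, ub=1, seed=0)
        x0 = np.array([[0.5, 0.5], [0.1, 0.1], [0.0, 0.0]])
        res = optimize(lambda x: float(np.sum((x - 0.5) ** 2)), p, x0=x0)
        assert res.f_best <= 0.0 + 1e-12  # init member already optimal


class TestSelectFeatures:
    def test_all_zero_position_means_empty_subset_fitness_one(self):
        # eval_fn that returns 0 everywhere: the empty subset still costs 1
        calls = []

        def ev(cols):
            calls.append(cols)
            return 0.0

        res = select_features(6, ev, SIAOParams(n_pop=4, n_iter=5, seed=0))
        assert all(len(c) > 0 for c in calls)
        assert res.fitness < 1.0

    def test_cardinality_only_objective_prefers_tiny_subsets(self):
        res = select_features(
            8, lambda cols: 0.0,
            SIAOParams(n_pop=10, n_iter=30, seed=1),
            weights=(0.0, 1.0, 0.0),
        )
        assert 1 <= len(res.selected) <= 2

    def test_su_prior_steers_ties(self):
        su = np.zeros(8)
        su[3] = 1.0
        res = select_features(
            8, lambda cols: 0.0,
            SIAOParams(n_pop=10, n_iter=40, seed=2),
            su_scores=su, weights=(0.0, 0.05, 0.5),
        )
        assert res.selected == (3,)

    def test_history_length_matches_iterations(self):
        res = select_features(5, lambda c: 0.5,
                              SIAOParams(n_pop=4, n_iter=7, seed=3))
        assert len(res.history) == 7
        assert np.all(np.diff(res.history) <= 0)
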