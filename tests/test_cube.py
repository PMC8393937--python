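"""Flight and landing phases of the cube method."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cubethin import (
    BalanceProblem,
    CubeState,
    flight_phase,
    flight_step,
    landing_phase,
    sample_direction,
    step_lengths,
)


def random_problem(n, j, seed, pi_range=(0.1, 0.9)):
    rng = np.random.default_rng(seed)
    pi = rng.uniform(*pi_range, size=n)
    a = rng.standard_normal((j, n))
    return BalanceProblem(pi=pi, a=a)


class TestSampleDirection:
    @pytest.mark.parametrize("strategy", ["naive", "fast"])
    def test_one_constraint_two_units(self, strategy):
        problem = BalanceProblem(pi=[0.5, 0.5], a=[[1.0, 1.0]])
        state = CubeState.from_problem(problem)
        u = sample_direction(state, problem, np.random.default_rng(0), strategy)
        assert u is not None
        # ker([1 1]) is spanned by (1, -1)
        assert u[0] == pytest.approx(-u[1])
        assert abs(u[0]) > 0

    def test_completion_when_all_integer(self):
        problem = BalanceProblem(pi=[1.0, 0.0, 1.0], a=[[1.0, 1.0, 1.0]])
        state = CubeState.from_problem(problem)
        assert sample_direction(state, problem, np.random.default_rng(0)) is None

    @pytest.mark.parametrize("strategy", ["naive", "fast"])
    def test_direction_in_kernel(self, strategy):
        problem = random_problem(50, 4, seed=0)
        state = CubeState.from_problem(problem)
        u = sample_direction(state, problem, np.random.default_rng(1), strategy)
        np.testing.assert_allclose(problem.a @ u, 0.0, atol=1e-9)
        assert np.all(u[state.is_integer] == 0.0)


class TestStepLengths:
    def test_center_of_square(self):
        assert step_lengths(np.array([0.5, 0.5]), np.array([1.0, -1.0])) == (0.5, 0.5)

    def test_componentwise_minimum(self):
        lam1, lam2 = step_lengths(np.array([0.9, 0.5]), np.array([1.0, -1.0]))
        assert lam1 == pytest.approx(0.1)
        assert lam2 == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True)
    @given(
        pi=st.lists(st.floats(0.05, 0.95), min_size=2, max_size=8),
        c=st.floats(0.1, 10.0),
        seed=st.integers(0, 100),
    )
    def test_homogeneous_in_direction_scale(self, pi, c, seed):
        pi = np.array(pi)
        u = np.random.default_rng(seed).standard_normal(pi.size)
        l1, l2 = step_lengths(pi, u)
        l1c, l2c = step_lengths(pi, c * u)
        assert l1c == pytest.approx(l1 / c)
        assert l2c == pytest.approx(l2 / c)


class TestFlightStep:
    def test_two_outcomes_with_equal_probability(self):
        """pi=(.5,.5) under a sum constraint resolves to (1,0) or (0,1),
        each with probability 1/2 (exhaustive two-outcome calculation)."""
        problem = BalanceProblem(pi=[0.5, 0.5], a=[[1.0, 1.0]])
        rng = np.random.default_rng(42)
        hits = Counter()
        for _ in range(10_000):
            state = CubeState.from_problem(problem)
            flight_step(state, problem, rng)
            hits[tuple(state.pi)] += 1
        assert set(hits) == {(1.0, 0.0), (0.0, 1.0)}
        assert stats.binomtest(hits[(1.0, 0.0)], 10_000, 0.5).pvalue > 1e-3

    def test_martingale_mean_preserved(self):
        problem = random_problem(6, 2, seed=3)
        rng = np.random.default_rng(5)
        acc = np.zeros(6)
        reps = 4000
        for _ in range(reps):
            state = CubeState.from_problem(problem)
            flight_step(state, problem, rng)
            acc += state.pi
        se = 0.5 / np.sqrt(reps)  # bound on the per-component SD
        np.testing.assert_allclose(acc / reps, problem.pi, atol=3.5 * se)

    def test_integer_count_increases(self):
        problem = random_problem(12, 3, seed=8)
        rng = np.random.default_rng(9)
        state = CubeState.from_problem(problem)
        before = state.is_integer.sum()
        flight_step(state, problem, rng)
        assert state.is_integer.sum() > before


class TestFlightPhase:
    def test_vertex_returned_unchanged(self):
        problem = BalanceProblem(pi=[1.0, 0.0, 1.0, 0.0], a=[[1.0, 1.0, 1.0, 1.0]])
        res = flight_phase(problem, np.random.default_rng(0))
        assert res.iterations == 0
        np.testing.assert_array_equal(res.pi_star, [1, 0, 1, 0])

    @pytest.mark.parametrize("strategy", ["naive", "fast"])
    def test_fractional_bound_and_conservation(self, strategy):
        problem = random_problem(100, 3, seed=1)
        trace: list = []
        res = flight_phase(problem, np.random.default_rng(2), strategy, trace=trace)
        frac = np.sum((res.pi_star > 0) & (res.pi_star < 1))
        assert frac <= 3
        target = problem.a @ problem.pi
        scale = max(1.0, np.abs(target).max())
        for pi_t in trace:
            np.testing.assert_allclose(
                problem.a @ pi_t, target, atol=1e-8 * scale
            )
        assert res.iterations <= 100

    def test_martingale_over_replicates(self):
        problem = random_problem(10, 2, seed=4)
        rng = np.random.default_rng(6)
        reps = 1000
        acc = np.zeros(10)
        for _ in range(reps):
            acc += flight_phase(problem, rng).pi_star
        mean = acc / reps
        z2 = reps * (mean - problem.pi) ** 2 / (problem.pi * (1 - problem.pi))
        assert z2.sum() < stats.chi2.ppf(0.99, 10)


class TestLandingPhase:
    def test_vertex_passthrough(self):
        problem = BalanceProblem(pi=[0.3, 0.7], a=[[1.0, 1.0]])
        s, diag = landing_phase(np.array([1.0, 0.0]), problem,
                                np.random.default_rng(0))
        np.testing.assert_array_equal(s, [1, 0])
        assert diag["dropped_rows"] == []

    def test_two_point_split(self):
        problem = BalanceProblem(pi=[0.5, 0.5], a=[[1.0, 1.0]])
        rng = np.random.default_rng(1)
        first = 0
        for _ in range(2000):
            s, _ = landing_phase(np.array([0.5, 0.5]), problem, rng)
            assert s.sum() == 1
            first += s[0]
        assert stats.binomtest(first, 2000, 0.5).pvalue > 1e-3

    def test_suppression_keeps_exact_size(self):
        """With the ones row first and an integer total, every landing
        vertex has exactly that many ones."""
        rng = np.random.default_rng(2)
        for seed in range(20):
            n = 12
            prng = np.random.default_rng(seed)
            pi = prng.uniform(0.1, 0.9, n)
            pi *= 4 / pi.sum()  # integer total
            a = np.vstack([np.ones(n), prng.standard_normal((2, n))])
            problem = BalanceProblem(pi=pi, a=a)
            res = flight_phase(problem, rng)
            s, _ = landing_phase(res.pi_star, problem, rng)
            assert s.sum() == 4

    def test_enumeration_preserves_expectation(self):
        n = 8
        prng = np.random.default_rng(7)
        pi = prng.uniform(0.2, 0.8, n)
        a = np.vstack([np.ones(n), prng.standard_normal((2, n))])
        problem = BalanceProblem(pi=pi, a=a)
        rng = np.random.default_rng(8)
        reps = 3000
        acc = np.zeros(n)
        for _ in range(reps):
            res = flight_phase(problem, rng)
            s, _ = landing_phase(res.pi_star, problem, rng,
                                 strategy="enumeration")
            acc += s
        mean = acc / reps
        z2 = reps * (mean - pi) ** 2 / (pi * (1 - pi))
        assert z2.sum() < stats.chi2.ppf(0.999, n)

    def test_enumeration_refuses_large_q(self):
        n = 40
        pi = np.full(n, 0.5)
        problem = BalanceProblem(pi=pi, a=np.ones((1, n)))
        with pytest.raises(ValueError, match="suppression"):
            landing_phase(pi, problem, np.random.default_rng(0),
                          strategy="enumeration")


class TestStrategyEquivalence:
    @pytest.mark.parametrize("strategy", ["naive", "fast"])
    def test_uniform_case_matches_enumeration(self, strategy):
        """Equal probabilities + size-2 constraint on 6 units: both
        direction strategies draw each of the 15 subsets uniformly."""
        problem = BalanceProblem(pi=np.full(6, 2 / 6), a=np.ones((1, 6)))
        rng = np.random.default_rng(10)
        counts = Counter()
        reps = 5000
        for _ in range(reps):
            res = flight_phase(problem, rng, strategy=strategy)
            s, _ = landing_phase(res.pi_star, problem, rng)
            counts[tuple(np.flatnonzero(s))] += 1
        obs = [counts.get(c, 0) for c in itertools.combinations(range(6), 2)]
        assert stats.chisquare(obs).pvalue > 0.01
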