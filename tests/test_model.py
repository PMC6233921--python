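"""Deterministic selection model: fitness evaluation, dynamics, crossings."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from normsel.model import (
    AncestralState,
    EnvironmentSchedule,
    FrequencyState,
    Lineage,
    ReactionNormParams,
    crossing_points,
    fitness_variance,
    lineage_log_fitness,
    mean_fitness,
    predict_trajectories,
    propagate_epoch,
    rwh_log_fitness,
    selfing_effective_size,
    step,
)


def lin(a, b):
    return ReactionNormParams("linear", (a, b))


def two_lineage_system(xi_a, xi_b):
    params = {"A": lin(0.0, xi_a), "B": lin(0.0, xi_b)}
    lineages = [Lineage("LA", ("A",)), Lineage("LB", ("B",))]
    return lineages, params


class TestReactionNorms:
    @pytest.mark.parametrize(
        "form,coef,x,expected",
        [
            ("linear", (0.0, math.log(2)), 100.0, math.log(2)),
            ("linear", (0.01, 0.0), 100.0, 1.0),
            ("quadratic", (1.0, 0.0, 0.0), -2.0, 4.0),
        ],
    )
    def test_rwh_log_fitness(self, form, coef, x, expected):
        assert rwh_log_fitness(x, ReactionNormParams(form, coef)) == pytest.approx(expected)

    def test_coefficient_count_enforced(self):
        with pytest.raises(ValueError):
            ReactionNormParams("linear", (1.0, 2.0, 3.0))
        with pytest.raises(ValueError):
            ReactionNormParams("cubic", (1.0, 2.0, 3.0))

    def test_lineage_log_fitness_is_additive(self):
        params = {
            "R1": lin(0.0, math.log(2)),
            "R2": lin(0.0, math.log(3)),
            "R3": lin(0.0, 0.0),
        }
        k = Lineage("L", ("R1", "R2", "R3"))
        assert math.exp(lineage_log_fitness(100.0, k, params)) == pytest.approx(6.0)

    def test_single_region_degenerates_to_rwh_norm(self):
        theta = lin(0.002, 0.3)
        k = Lineage("L", ("R1",))
        x = 150.0
        assert lineage_log_fitness(x, k, {"R1": theta}) == rwh_log_fitness(x, theta)

    def test_missing_rwh_named_in_error(self):
        with pytest.raises(KeyError, match="R9"):
            lineage_log_fitness(1.0, Lineage("L", ("R9",)), {})


class TestStep:
    def test_hand_normalization(self):
        lineages, params = two_lineage_system(math.log(2.0), 0.0)
        state = FrequencyState.from_frequencies(0, [0.5, 0.5])
        out = step(state, 100.0, lineages, params)
        np.testing.assert_allclose(out.frequencies, [2 / 3, 1 / 3], rtol=1e-12)

    def test_neutral_invariance(self):
        lineages, params = two_lineage_system(0.7, 0.7)
        state = FrequencyState.from_frequencies(0, [0.3, 0.7])
        out = step(state, 200.0, lineages, params)
        np.testing.assert_allclose(out.frequencies, [0.3, 0.7], rtol=1e-12)

    def test_boundary_is_fixed(self):
        lineages, params = two_lineage_system(0.0, 5.0)
        state = FrequencyState.from_frequencies(0, [1.0, 0.0])
        out = step(state, 100.0, lineages, params)
        np.testing.assert_allclose(out.frequencies, [1.0, 0.0])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        g=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
        xis=st.lists(st.floats(-2.0, 2.0), min_size=2, max_size=6),
    )
    def test_simplex_conserved(self, g, xis):
        n = min(len(g), len(xis))
        g = np.array(g[:n]) / np.sum(g[:n])
        params = {f"H{i}": lin(0.0, xis[i]) for i in range(n)}
        lineages = [Lineage(f"L{i}", (f"H{i}",)) for i in range(n)]
        out = step(FrequencyState.from_frequencies(0, g), 100.0, lineages, params)
        assert abs(out.frequencies.sum() - 1.0) < 1e-12
        assert (out.frequencies >= 0).all()


class TestPropagation:
    def test_two_lineage_logistic_closed_form(self):
        # constant environment: logit(g_1) gains exactly t * (xi_1 - xi_2)
        dxi = 0.13
        lineages, params = two_lineage_system(dxi, 0.0)
        sched = EnvironmentSchedule("const", [1], [100.0])
        g0 = 0.2
        states = predict_trajectories(
            AncestralState(lineages, np.array([g0, 1 - g0])), sched, 40, params
        )
        logit = lambda p: math.log(p / (1 - p))
        for t in (1, 10, 40):
            got = logit(states[t].frequencies[0]) - logit(g0)
            assert got == pytest.approx(t * dxi, abs=1e-10)

    def test_epoch_product_equals_sequential_steps(self):
        rng = np.random.default_rng(3)
        params = {f"H{i}": lin(rng.uniform(-0.004, 0.004), rng.uniform(-0.5, 1.0)) for i in range(4)}
        lineages = [Lineage(f"L{i}", (f"H{i}",)) for i in range(4)]
        sched = EnvironmentSchedule.gradual()
        state = FrequencyState.from_frequencies(0, rng.dirichlet(np.ones(4)))
        seq = state
        for t in range(1, 36):
            seq = step(seq, sched.value_at(t), lineages, params)
        bulk = propagate_epoch(state, sched, 0, 35, lineages, params)
        np.testing.assert_allclose(bulk.frequencies, seq.frequencies, atol=1e-10)

    def test_epoch_split_composes(self):
        rng = np.random.default_rng(4)
        params = {f"H{i}": lin(rng.uniform(-0.004, 0.004), rng.uniform(-0.5, 1.0)) for i in range(3)}
        lineages = [Lineage(f"L{i}", (f"H{i}",)) for i in range(3)]
        sched = EnvironmentSchedule.gradual()
        state = FrequencyState.from_frequencies(0, rng.dirichlet(np.ones(3)))
        whole = propagate_epoch(state, sched, 0, 50, lineages, params)
        part = propagate_epoch(state, sched, 0, 17, lineages, params)
        part = propagate_epoch(part, sched, 17, 50, lineages, params)
        np.testing.assert_allclose(whole.frequencies, part.frequencies, atol=1e-10)
        assert whole.generation == part.generation == 50

    def test_single_generation_epoch_equals_step(self):
        lineages, params = two_lineage_system(0.4, 0.1)
        sched = EnvironmentSchedule("const", [1], [50.0])
        state = FrequencyState.from_frequencies(0, [0.4, 0.6])
        np.testing.assert_allclose(
            propagate_epoch(state, sched, 0, 1, lineages, params).frequencies,
            step(state, 50.0, lineages, params).frequencies,
            rtol=1e-14,
        )

    def test_schedule_gap_raises(self):
        sched = EnvironmentSchedule("late", [5], [100.0])
        lineages, params = two_lineage_system(0.1, 0.0)
        state = FrequencyState.from_frequencies(0, [0.5, 0.5])
        with pytest.raises(KeyError, match="generation 1"):
            propagate_epoch(state, sched, 0, 10, lineages, params)

    def test_trajectory_length_and_simplex(self):
        lineages, params = two_lineage_system(0.3, 0.0)
        anc = AncestralState(lineages, np.array([0.1, 0.9]))
        states = predict_trajectories(anc, EnvironmentSchedule.sudden(), 25, params)
        assert len(states) == 26
        for s in states:
            assert abs(s.frequencies.sum() - 1.0) < 1e-12

    def test_dominant_lineage_sweeps_monotonically(self):
        lineages, params = two_lineage_system(0.5, 0.0)
        anc = AncestralState(lineages, np.array([0.01, 0.99]))
        states = predict_trajectories(anc, EnvironmentSchedule.sudden(), 30, params)
        f = [s.frequencies[0] for s in states]
        assert all(b > a for a, b in zip(f, f[1:]))


class TestFitnessMoments:
    def test_hand_values(self):
        lineages, params = two_lineage_system(math.log(2.0), math.log(4.0))
        state = FrequencyState.from_frequencies(0, [0.5, 0.5])
        assert mean_fitness(state, 1.0, lineages, params) == pytest.approx(3.0)
        assert fitness_variance(state, 1.0, lineages, params) == pytest.approx(1.0)

    def test_monomorphic_state(self):
        lineages, params = two_lineage_system(math.log(5.0), 0.0)
        state = FrequencyState.from_frequencies(0, [1.0, 0.0])
        assert mean_fitness(state, 0.0, lineages, params) == pytest.approx(5.0)
        assert fitness_variance(state, 0.0, lineages, params) == pytest.approx(0.0)

    def test_mean_fitness_monotone_in_constant_environment(self):
        # haploid Fisher property, checked on randomized instances
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(2, 6))
            params = {
                f"H{i}": lin(rng.uniform(-0.005, 0.005), rng.uniform(-1.0, 1.0))
                for i in range(n)
            }
            lineages = [Lineage(f"L{i}", (f"H{i}",)) for i in range(n)]
            x = float(rng.uniform(25, 305))
            state = FrequencyState.from_frequencies(0, rng.dirichlet(np.ones(n)))
            prev = mean_fitness(state, x, lineages, params)
            for _ in range(20):
                state = step(state, x, lineages, params)
                cur = mean_fitness(state, x, lineages, params)
                assert cur >= prev - 1e-12
                prev = cur


class TestCrossingPoints:
    def test_linear_closed_form(self):
        params = {"A": lin(0.02, 0.0), "B": lin(0.0, 5.0)}
        roots = crossing_points(Lineage("a", ("A",)), Lineage("b", ("B",)), params, (0, 400))
        assert roots == pytest.approx([250.0])

    def test_parallel_distinct_is_empty(self):
        params = {"A": lin(0.01, 0.0), "B": lin(0.01, 1.0)}
        assert crossing_points(Lineage("a", ("A",)), Lineage("b", ("B",)), params, (0, 400)) == []

    def test_negative_discriminant_is_empty(self):
        params = {
            "A": ReactionNormParams("quadratic", (1.0, 0.0, 1.0)),
            "B": ReactionNormParams("quadratic", (0.0, 0.0, 0.0)),
        }
        assert crossing_points(Lineage("a", ("A",)), Lineage("b", ("B",)), params, (-10, 10)) == []

    def test_identical_norms_raise(self):
        params = {"A": lin(0.01, 0.5), "B": lin(0.01, 0.5)}
        with pytest.raises(ValueError, match="coincide"):
            crossing_points(Lineage("a", ("A",)), Lineage("b", ("B",)), params, (0, 400))

    def test_matches_bisection_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            params = {
                f"{side}{r}": lin(rng.uniform(-0.005, 0.005), rng.uniform(-0.5, 0.5))
                for side in "AB"
                for r in range(3)
            }
            a = Lineage("a", tuple(f"A{r}" for r in range(3)))
            b = Lineage("b", tuple(f"B{r}" for r in range(3)))
            diff = lambda x: lineage_log_fitness(x, a, params) - lineage_log_fitness(x, b, params)
            roots = crossing_points(a, b, params, (25.0, 305.0))
            if diff(25.0) * diff(305.0) < 0:
                oracle = brentq(diff, 25.0, 305.0, xtol=1e-9)
                assert len(roots) == 1
                assert roots[0] == pytest.approx(oracle, abs=1e-6)
            else:
                assert roots == []


class TestSchedules:
    def test_builtin_gradual_endpoints(self):
        s = EnvironmentSchedule.gradual()
        assert s.value_at(1) == 33.0
        assert s.value_at(2) == 41.0
        assert s.value_at(35) == 305.0
        assert s.value_at(36) == 305.0
        assert s.value_at(100) == 305.0

    def test_builtin_sudden_and_control(self):
        assert EnvironmentSchedule.sudden().value_at(1) == 305.0
        assert EnvironmentSchedule.control().value_at(50) == 25.0

    def test_sparse_rows_fill_forward(self):
        s = EnvironmentSchedule("x", [1, 10], [50.0, 80.0])
        assert s.value_at(5) == 50.0
        assert s.value_at(10) == 80.0
        np.testing.assert_allclose(s.values(8, 11), [50.0, 80.0, 80.0])

    def test_query_before_first_breakpoint_raises(self):
        s = EnvironmentSchedule("x", [5], [50.0])
        with pytest.raises(KeyError):
            s.value_at(2)


def test_selfing_halves_effective_size():
    assert selfing_effective_size(1000.0) == 500.0
    with pytest.raises(ValueError):
        selfing_effective_size(0.0)
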