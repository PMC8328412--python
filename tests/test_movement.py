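import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import kstest, norm

from pikasim.config import SimulationConfig
from pikasim.movement import (
    PikaState,
    advance,
    check_return,
    expected_daily_distance,
    sample_speed,
    simulate_day,
    simulate_population_day,
    wrap,
)
from pikasim.territory import generate_landscape


class TestSampleSpeed:
    def test_high_intensity_moments(self, rng):
        cfg = SimulationConfig()
        draws = sample_speed("high", cfg, rng, size=100_000)
        assert draws.mean() == pytest.approx(20.0, abs=0.05)
        assert draws.std() == pytest.approx(2.0, abs=0.05)

    def test_zero_sigma_is_deterministic(self, rng):
        cfg = SimulationConfig(sigma_large=0.0)
        draws = sample_speed("high", cfg, rng, size=100)
        np.testing.assert_array_equal(draws, 20.0)

    def test_low_intensity_truncation_negligible(self, rng):
        # closed-form normal CDF oracle: P(draw < 0) = Phi(-v/sigma) = Phi(-10)
        assert norm.cdf(-2.0 / 0.2) < 1e-20
        cfg = SimulationConfig()
        draws = sample_speed("low", cfg, rng, size=100_000)
        assert (draws == 0.0).sum() == 0
        assert draws.mean() == pytest.approx(2.0, abs=0.01)

    def test_bad_intensity(self, rng):
        with pytest.raises(ValueError):
            sample_speed("medium", SimulationConfig(), rng)


class TestWrap:
    def test_interior_unchanged(self):
        np.testing.assert_array_equal(wrap([500.0, 500.0], 1000.0), [500.0, 500.0])

    def test_overflow(self):
        np.testing.assert_allclose(wrap([1001.0, 500.0], 1000.0), [1.0, 500.0])

    def test_negative(self):
        np.testing.assert_allclose(wrap([-1.0, -1.0], 1000.0), [999.0, 999.0])

    @given(
        x=st.floats(-1e4, 1e4, allow_nan=False),
        k=st.integers(-5, 5),
    )
    def test_modular_identity(self, x, k):
        L = 1000.0
        w = wrap([x, 0.0], L)
        assert 0 <= w[0] < L
        w2 = wrap([x + k * L, 0.0], L)
        assert w2[0] == pytest.approx(w[0], abs=1e-6)


class TestCheckReturn:
    ENT = np.array([[10.0, 10.0], [20.0, 10.0]])

    def test_exactly_at_entrance(self):
        assert check_return([10.0, 10.0], self.ENT, 1.0)

    def test_within_threshold(self):
        assert check_return([10.5, 10.0], self.ENT, 1.0)

    def test_boundary_is_strict(self):
        assert not check_return([11.0, 10.0], self.ENT, 1.0)

    def test_empty_entrances_error(self):
        with pytest.raises(ValueError):
            check_return([0.0, 0.0], np.empty((0, 2)), 1.0)


class TestAdvance:
    def _state(self, budget=10.0):
        return PikaState(
            id=0, system_id=0, position=np.array([100.0, 100.0]),
            status="outside", budget_remaining=budget,
        )

    def test_displacement_matches_speed(self, rng):
        cfg = SimulationConfig(sigma_large=0.0, p_high=1.0, L=1000.0)
        state = self._state()
        p0 = state.position.copy()
        advance(state, cfg, rng)
        # dt = 0.5 min at 20 m/min -> 10 m displacement
        assert state.step_distance == pytest.approx(10.0)
        assert np.linalg.norm(state.position - p0) == pytest.approx(10.0)
        assert state.budget_remaining == pytest.approx(9.5)

    def test_zero_speed_keeps_position(self, rng):
        cfg = SimulationConfig(v_small=1e-12, sigma_small=0.0, p_high=0.0)
        state = self._state()
        p0 = state.position.copy()
        advance(state, cfg, rng)
        np.testing.assert_allclose(state.position, p0, atol=1e-9)

    def test_inside_is_contract_violation(self, rng):
        state = self._state()
        state.status = "inside"
        with pytest.raises(RuntimeError):
            advance(state, SimulationConfig(), rng)

    def test_headings_uniform_ks(self, rng):
        cfg = SimulationConfig()
        headings = []
        for _ in range(10_000):
            state = self._state()
            advance(state, cfg, rng)
            headings.append(state.heading)
        stat, p = kstest(np.array(headings) / (2 * math.pi), "uniform")
        assert p > 0.01

    def test_step_capped_at_d_max(self, rng):
        cfg = SimulationConfig(d_max=3.0, sigma_large=0.0, p_high=1.0)
        state = self._state()
        advance(state, cfg, rng)
        assert state.step_distance == pytest.approx(3.0)


@pytest.fixture(scope="module")
def tiny_landscape():
    cfg = SimulationConfig(L=100.0, n_systems=25, H_min=3, H_max=5,
                           Q_min=1, Q_max=2, t_tol=10.0)
    return cfg, generate_landscape(cfg, seed=1)


class TestSimulateDay:
    def test_zero_budget_empty_path(self, tiny_landscape, rng):
        cfg, ls = tiny_landscape
        path = simulate_day(0, 0, ls, cfg.replace(t_tol=0.0, dt=0.5), rng)
        assert path.segments == []
        assert path.total_distance == 0.0

    def test_budget_conservation(self, tiny_landscape, rng):
        cfg, ls = tiny_landscape
        path = simulate_day(0, 0, ls, cfg, rng)
        # t_tol = 10 min, dt = 0.5 -> exactly 20 outside steps
        assert len(path.segments) == 20

    def test_budget_non_multiple_of_dt(self, tiny_landscape, rng):
        cfg, ls = tiny_landscape
        path = simulate_day(0, 0, ls, cfg.replace(t_tol=10.2), rng)
        assert len(path.segments) == 21  # <= t_tol + dt of outside time

    def test_segments_contiguous_and_consistent(self, tiny_landscape, rng):
        cfg, ls = tiny_landscape
        path = simulate_day(0, 3, ls, cfg, rng)
        total = 0.0
        for t, p0, p1 in path.segments:
            step = np.linalg.norm(p1 - p0)
            assert 0.0 <= step <= cfg.d_max + 1e-12
            total += step
        assert total == pytest.approx(path.total_distance)
        # time stamps advance by dt
        times = [t for t, _, _ in path.segments]
        np.testing.assert_allclose(np.diff(times), cfg.dt)

    def test_wrap_continuity(self, tiny_landscape, rng):
        cfg, ls = tiny_landscape
        path = simulate_day(0, 0, ls, cfg, rng)
        excursion_restarts = 0
        for (t0, a0, a1), (t1, b0, b1) in zip(path.segments, path.segments[1:]):
            if not np.allclose(b0, np.mod(a1, cfg.L)):
                excursion_restarts += 1  # teleport to a new exit entrance
        assert excursion_restarts <= len(path.excursions)

    def test_huge_l_home_single_step_excursions(self, tiny_landscape, rng):
        cfg, ls = tiny_landscape
        path = simulate_day(0, 0, ls, cfg.replace(l_home=1e9), rng)
        assert len(path.excursions) == len(path.segments)
        assert all(ret is not None for _, ret in path.excursions)

    def test_zero_l_home_single_excursion(self, tiny_landscape, rng):
        cfg, ls = tiny_landscape
        path = simulate_day(0, 0, ls, cfg.replace(l_home=0.0), rng)
        assert len(path.excursions) == 1
        assert path.excursions[0][1] is None  # ends only by budget exhaustion


class TestDailyDistance:
    def test_population_mean_matches_closed_form(self):
        # validation settings: t_tol=15, v mix (20, 2) at p=0.5 -> E = 165 m
        cfg = SimulationConfig(L=300.0, n_systems=225, t_tol=15.0, seed=2)
        assert expected_daily_distance(cfg) == pytest.approx(165.0)
        ls = generate_landscape(cfg, seed=2)
        batch = simulate_population_day(ls, cfg, np.random.default_rng(0))
        n = batch.n_pikas
        assert n >= 1000
        se = batch.total_distance.std(ddof=1) / math.sqrt(n)
        assert abs(batch.total_distance.mean() - 165.0) <= 3 * se

    def test_parameter_recovery_other_settings(self):
        cfg = SimulationConfig(L=200.0, n_systems=100, t_tol=10.0,
                               p_high=0.3, seed=4)
        expect = 20 * 0.5 * (0.3 * 20 + 0.7 * 2)
        assert expected_daily_distance(cfg) == pytest.approx(expect)
        ls = generate_landscape(cfg, seed=4)
        batch = simulate_population_day(ls, cfg, np.random.default_rng(1))
        se = batch.total_distance.std(ddof=1) / math.sqrt(batch.n_pikas)
        assert abs(batch.total_distance.mean() - expect) <= 3.5 * se

    def test_engines_agree_statistically(self, tiny_landscape):
        cfg, ls = tiny_landscape
        batch = simulate_population_day(ls, cfg, np.random.default_rng(5))
        sys_idx = ls.pika_system_index()
        ref = [
            simulate_day(i, int(sys_idx[i]), ls, cfg, np.random.default_rng(100 + i))
            .total_distance
            for i in range(len(sys_idx))
        ]
        ref = np.array(ref)
        se = math.sqrt(
            batch.total_distance.var(ddof=1) / batch.n_pikas
            + ref.var(ddof=1) / len(ref)
        )
        assert abs(batch.total_distance.mean() - ref.mean()) <= 3.5 * se


class TestPopulationEngine:
    def test_deterministic(self, tiny_landscape):
        cfg, ls = tiny_landscape
        a = simulate_population_day(ls, cfg, np.random.default_rng(9))
        b = simulate_population_day(ls, cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(a.p0, b.p0)
        np.testing.assert_array_equal(a.p1, b.p1)

    def test_segment_shapes_and_bounds(self, tiny_landscape):
        cfg, ls = tiny_landscape
        batch = simulate_population_day(ls, cfg, np.random.default_rng(6))
        assert batch.p0.shape == (ls.n_pikas, cfg.n_steps_per_day, 2)
        # starts are wrapped; displacement <= d_max
        assert batch.p0.min() >= 0 and batch.p0.max() <= cfg.L
        step = np.linalg.norm(batch.p1 - batch.p0, axis=2)
        assert step.max() <= cfg.d_max + 1e-12
        np.testing.assert_allclose(step.sum(axis=1), batch.total_distance)

    def test_zero_budget(self, tiny_landscape):
        cfg, ls = tiny_landscape
        batch = simulate_population_day(ls, cfg.replace(t_tol=0.0, dt=0.5),
                                        np.random.default_rng(0))
        assert batch.n_steps == 0
        np.testing.assert_array_equal(batch.total_distance, 0.0)
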