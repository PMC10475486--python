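"""Within-cycle gLV dynamics: derivatives, integration, extinction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chainstab import (
    MetaCommunityState,
    SpeciesPool,
    apply_extinction_threshold,
    integrate_cycle,
    realized_growth_rates,
    rhs_metacommunity,
)
from chainstab.dynamics import step_cycle

from conftest import random_state


class TestRHS:
    def test_hand_example(self, two_species_pool):
        state = MetaCommunityState([1.0, 1.0], [0.0, 0.0])
        d1, d2 = rhs_metacommunity(state, two_species_pool)
        np.testing.assert_allclose(d1, [0.5, -0.5])
        np.testing.assert_allclose(d2, [0.0, 0.0])

    def test_monoculture_equilibrium_is_r(self):
        pool = SpeciesPool(r1=[0.7], r2=[0.3], A=[[-1.0]])
        state = MetaCommunityState([0.7], [0.0])
        d1, _ = rhs_metacommunity(state, pool)
        assert d1[0] == pytest.approx(0.0, abs=1e-15)

    def test_all_zero_state_has_zero_derivative(self, random_pool):
        state = MetaCommunityState.empty(random_pool.N)
        d1, d2 = rhs_metacommunity(state, random_pool)
        assert np.all(d1 == 0) and np.all(d2 == 0)

    def test_one_way_coupling(self, random_pool, rng):
        """Downstream abundances never feed back into upstream derivatives."""
        s1 = random_state(random_pool, rng)
        s2 = MetaCommunityState(s1.x1.copy(), rng.uniform(0, 2, random_pool.N))
        d1a, _ = rhs_metacommunity(s1, random_pool)
        d1b, _ = rhs_metacommunity(s2, random_pool)
        np.testing.assert_array_equal(d1a, d1b)

    def test_dimension_mismatch_raises(self, two_species_pool):
        state = MetaCommunityState([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            rhs_metacommunity(state, two_species_pool)

    def test_nan_state_raises(self, two_species_pool):
        state = MetaCommunityState([1.0, 1.0], [0.0, 0.0])
        state.x1[0] = np.nan
        with pytest.raises(ValueError):
            rhs_metacommunity(state, two_species_pool)


class TestRealizedGrowthRates:
    def test_empty_upstream_gives_baseline(self, random_pool):
        rhat = realized_growth_rates(np.zeros(random_pool.N), random_pool)
        np.testing.assert_array_equal(rhat, random_pool.r2)

    def test_single_upstream_contribution(self):
        pool = SpeciesPool(
            r1=[0.5, 0.5], r2=[0.4, 0.6], A=[[-1.0, 0.3], [0.0, -1.0]]
        )
        rhat = realized_growth_rates(np.array([0.0, 2.0]), pool)
        assert rhat[0] == pytest.approx(0.4 + 0.6)

    def test_decomposition_matches_direct_rhs(self, random_pool, rng):
        """gLV downstream derivative == x2 * (rhat + A @ x2) elementwise."""
        state = random_state(random_pool, rng)
        _, d2 = rhs_metacommunity(state, random_pool)
        rhat = realized_growth_rates(state.x1, random_pool)
        expected = state.x2 * (rhat + random_pool.A @ state.x2)
        np.testing.assert_allclose(d2, expected, rtol=1e-12)


class TestIntegrateCycle:
    def test_monoculture_converges_to_r(self):
        pool = SpeciesPool(r1=[0.8], r2=[0.1], A=[[-1.0]])
        state = MetaCommunityState([0.01], [0.0])
        traj = integrate_cycle(state, pool)
        assert traj.converged
        assert abs(traj.final.x1[0] - 0.8) < 1e-4

    def test_monoculture_matches_logistic_closed_form(self):
        r, x0, t_end = 0.8, 0.01, 40.0
        pool = SpeciesPool(r1=[r], r2=[0.1], A=[[-1.0]])
        state = MetaCommunityState([x0], [0.0])
        traj = integrate_cycle(state, pool, duration=t_end, n_out=9)
        for t, s in zip(traj.times, traj.states):
            expected = r * x0 * np.exp(r * t) / (r + x0 * (np.exp(r * t) - 1.0))
            assert s.x1[0] == pytest.approx(expected, rel=1e-6)

    def test_competitive_exclusion(self):
        """Strong mutual competition started asymmetrically excludes one."""
        pool = SpeciesPool(
            r1=[1.0, 1.0], r2=[1.0, 1.0],
            A=np.array([[-1.0, -2.0], [-2.0, -1.0]]),
        )
        state = MetaCommunityState([0.9, 0.1], [0.0, 0.0])
        final = integrate_cycle(state, pool).final
        assert final.x1[1] == 0.0 and final.x1[0] > 0.5

    def test_absence_is_absorbing(self, random_pool, rng):
        state = random_state(random_pool, rng)
        absent = state.x1 == 0
        final = integrate_cycle(state, random_pool).final
        assert np.all(final.x1[absent] == 0.0)

    def test_nonnegative_along_trajectory(self, random_pool, rng):
        state = random_state(random_pool, rng)
        traj = integrate_cycle(state, random_pool, n_out=31)
        for s in traj.states:
            assert np.all(s.x1 >= 0) and np.all(s.x2 >= 0)

    def test_deterministic(self, random_pool, rng):
        state = random_state(random_pool, rng)
        f1 = integrate_cycle(state.copy(), random_pool).final
        f2 = integrate_cycle(state.copy(), random_pool).final
        np.testing.assert_array_equal(f1.x1, f2.x1)
        np.testing.assert_array_equal(f1.x2, f2.x2)

    def test_times_span_cycle(self, random_pool, rng):
        traj = integrate_cycle(random_state(random_pool, rng), random_pool, n_out=5)
        assert traj.times[0] == 0.0 and traj.times[-1] == 300.0
        assert np.all(np.diff(traj.times) > 0)

    def test_step_cycle_advances_counter(self, random_pool, rng):
        state = random_state(random_pool, rng)
        out, ok = step_cycle(state, random_pool)
        assert out.cycle == state.cycle + 1


class TestExtinctionThreshold:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([1e-9, 0.5], [0.0, 0.5]),
            ([0.5, 0.2], [0.5, 0.2]),
            ([0.0, 1e-7, 1e-5], [0.0, 0.0, 1e-5]),
        ],
    )
    def test_examples(self, x, expected):
        np.testing.assert_array_equal(
            apply_extinction_threshold(np.array(x), 1e-6), expected
        )

    def test_idempotent(self, rng):
        x = rng.uniform(0, 1e-5, 50)
        once = apply_extinction_threshold(x)
        twice = apply_extinction_threshold(once)
        np.testing.assert_array_equal(once, twice)

    def test_nonpositive_threshold_raises(self):
        with pytest.raises(ValueError):
            apply_extinction_threshold(np.array([1.0]), 0.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_realized_growth_decomposition_property(seed):
    """Rewriting the downstream equation through realized growth rates is an
    algebraic identity on random instances."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 7))
    A = rng.normal(0, 0.3, (n, n))
    np.fill_diagonal(A, -1.0)
    pool = SpeciesPool(rng.uniform(0, 1, n), rng.uniform(0, 1, n), A)
    x1 = rng.uniform(0, 2, n)
    x2 = rng.uniform(0, 2, n)
    state = MetaCommunityState(x1, x2)
    _, d2 = rhs_metacommunity(state, pool)
    rhat = realized_growth_rates(x1, pool)
    np.testing.assert_allclose(d2, x2 * (rhat + A @ x2), rtol=1e-10, atol=1e-12)
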