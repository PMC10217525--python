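"""Exact stochastic simulation of the driven two-state channel."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import kstest, ks_2samp

from mscs_erasure import (
    ChannelParams,
    closing_rate,
    equilibrium_popen,
    make_erasure_ramp,
    make_hold,
    mean_occupancy,
    opening_rate,
    simulate_ensemble,
    simulate_trajectory,
)
from mscs_erasure.simulator import OPENING, CLOSING, sample_transition_time


def first_opening_tension_oracle(params, gamma_a, gamma_b, duration, q):
    """Quantile of the first-opening tension on a linear ramp, closed form.

    Solves Lambda(t) = -ln(1-q) with Lambda(t) = A(e^{Bt}-1)/B for the
    opening hazard A = k_open(gamma_a), B = dA_cB * slope.
    """
    c = (gamma_b - gamma_a) / duration
    a = opening_rate(params, gamma_a)
    b = params.area_closed_to_barrier * c
    target = -math.log(1.0 - q)
    lam = lambda t: a * (math.exp(b * t) - 1.0) / b
    t_q = brentq(lambda t: lam(t) - target, 0.0, duration)
    return gamma_a + c * t_q


class TestSampleTransitionTime:
    def test_constant_rate_inversion(self, params, gamma_mid):
        """On a hold the sampler is a plain exponential draw: E = k*dt."""

        class FixedExp:
            def exponential(self):
                return 0.7

        k = opening_rate(params, gamma_mid)
        t = sample_transition_time(params, 0, 0.0, gamma_mid, 2.0, 100.0, FixedExp())
        assert t == pytest.approx(2.0 + 0.7 / k, rel=1e-12)

    def test_bounded_hazard_survival(self, params):
        """For a decreasing rate (B<0) a large draw means guaranteed survival."""

        class BigExp:
            def exponential(self):
                return 1e9

        # open channel on an up-ramp: closing rate decays, hazard bounded
        t = sample_transition_time(params, 1, 1.0, 2.0, 0.0, 50.0, BigExp())
        assert t is None

    def test_zero_length_segment_rejected(self, params, rng):
        with pytest.raises(ValueError):
            sample_transition_time(params, 0, 1.0, 1.9, 1.0, 1.0, rng)

    def test_first_opening_median_matches_closed_form(self, params, gamma_mid, fast_ramp):
        trajs = simulate_ensemble(params, fast_ramp, 4000, "fixed_closed", 99)
        tensions = [t.events[0].tension_at_event for t in trajs if t.events]
        med_oracle = first_opening_tension_oracle(params, gamma_mid, 3.0, 0.25, 0.5)
        assert med_oracle == pytest.approx(2.232, abs=5e-3)  # frozen closed form
        assert np.median(tensions) == pytest.approx(med_oracle, abs=0.02)

    def test_first_opening_distribution_vs_bernoulli_oracle(self, params, gamma_mid):
        """Exact inversion sampler vs a dt=1e-5 Bernoulli discretization.

        The two first-opening-tension samples must be KS-indistinguishable
        at alpha = 0.01 with 5,000 draws per arm.
        """
        n = 5000
        duration, dt = 0.25, 1e-5
        ramp = make_erasure_ramp(gamma_mid, 3.0, duration)
        trajs = simulate_ensemble(params, ramp, n, "fixed_closed", 2024)
        exact = np.array([t.events[0].time for t in trajs if t.events])

        steps = int(duration / dt)
        grid = gamma_mid + (3.0 - gamma_mid) / duration * (np.arange(steps) * dt)
        p_step = params.k_open_0 * np.exp(params.area_closed_to_barrier * grid) * dt
        rng = np.random.default_rng(777)
        times = []
        for start in range(0, n, 500):
            m = min(500, n - start)
            fired = rng.random((m, steps)) < p_step
            idx = fired.argmax(axis=1)
            hit = fired.any(axis=1)
            times.append((idx[hit] + 1) * dt)
        oracle = np.concatenate(times)
        stat, pval = ks_2samp(exact, oracle)
        assert pval > 0.01, f"KS p={pval:.4g}, D={stat:.4g}"

    def test_hold_waiting_times_exponential(self, params, gamma_mid):
        """Inter-event openings on a hold follow Exp(k_open) (KS test)."""
        hold = make_hold(gamma_mid, 5000.0)
        k = opening_rate(params, gamma_mid)
        rng = np.random.default_rng(5)
        waits = []
        t0 = 0.0
        traj = simulate_trajectory(params, hold, 0, rng)
        state = 0
        last = 0.0
        for ev in traj.events:
            if ev.direction == OPENING:
                waits.append(ev.time - last)
            last = ev.time
        stat, pval = kstest(np.array(waits) * k, "expon")
        assert len(waits) > 1000
        assert pval > 0.01


class TestTrajectory:
    def test_frozen_rates_give_empty_event_list(self, fast_ramp, rng):
        p = ChannelParams(k_open_0=1e-300, k_close_0=1e-300)
        traj = simulate_trajectory(p, fast_ramp, 0, rng)
        assert traj.events == ()

    def test_directions_alternate_from_initial_state(self, params, gamma_mid, rng):
        prot = make_hold(gamma_mid, 50.0)
        for s0, first in [(0, OPENING), (1, CLOSING)]:
            traj = simulate_trajectory(params, prot, s0, np.random.default_rng(8))
            assert traj.events[0].direction == first
            dirs = [ev.direction for ev in traj.events]
            assert all(a != b for a, b in zip(dirs, dirs[1:]))

    def test_event_times_strictly_increasing_with_matching_tension(
        self, params, fast_ramp, rng
    ):
        traj = simulate_trajectory(params, fast_ramp, 0, rng)
        times = [ev.time for ev in traj.events]
        assert all(b > a for a, b in zip(times, times[1:]))
        for ev in traj.events:
            assert ev.tension_at_event == pytest.approx(
                fast_ramp.tension_at(ev.time), abs=1e-12)

    def test_fast_ramp_ends_open(self, params, fast_ramp):
        """Survival of the opening hazard to gamma=3 is ~5e-69: all end open."""
        trajs = simulate_ensemble(params, fast_ramp, 500, "fixed_closed", 4)
        assert all(t.state_at(fast_ramp.total_duration) == 1 for t in trajs)

    def test_hold_occupancy_matches_boltzmann(self, params):
        """Long-hold fraction of time open approaches equilibrium P_open."""
        gamma = 1.9
        hold = make_hold(gamma, 2000.0)
        traj = simulate_trajectory(params, hold, 0, np.random.default_rng(17))
        t_open, last, state = 0.0, 0.0, 0
        for ev in traj.events:
            if state == 1:
                t_open += ev.time - last
            last, state = ev.time, (1 if ev.direction == OPENING else 0)
        if state == 1:
            t_open += hold.total_duration - last
        frac = t_open / hold.total_duration
        p_eq = equilibrium_popen(params, gamma)
        # ~2400 events over the hold: generous 3-sigma-ish band
        assert frac == pytest.approx(p_eq, abs=0.03)


class TestEnsemble:
    def test_same_seed_reproduces_ensemble(self, params, fast_ramp):
        a = simulate_ensemble(params, fast_ramp, 50, "equilibrium_at_start", 31)
        b = simulate_ensemble(params, fast_ramp, 50, "equilibrium_at_start", 31)
        assert a == b

    def test_equilibrium_init_is_fair_coin_at_midpoint(self, params, fast_ramp):
        trajs = simulate_ensemble(params, fast_ramp, 2000, "equilibrium_at_start", 6)
        frac_open = np.mean([t.initial_state for t in trajs])
        assert frac_open == pytest.approx(0.5, abs=3 * 0.5 / math.sqrt(2000))

    def test_invalid_inputs_rejected(self, params, fast_ramp):
        with pytest.raises(ValueError):
            simulate_ensemble(params, fast_ramp, 0)
        with pytest.raises(ValueError):
            simulate_ensemble(params, fast_ramp, 5, "bogus_mode")
        with pytest.raises(ValueError):
            simulate_trajectory(params, fast_ramp, 2, np.random.default_rng(0))

    def test_hold_ensemble_mean_occupancy(self, params):
        """Equilibrium-initialized hold stays at the Boltzmann occupancy."""
        gamma = 2.1
        hold = make_hold(gamma, 1.0)
        trajs = simulate_ensemble(params, hold, 3000, "equilibrium_at_start", 13)
        grid = [0.0, 0.5, 1.0]
        occ = mean_occupancy(trajs, grid)
        p_eq = equilibrium_popen(params, gamma)
        se = math.sqrt(p_eq * (1 - p_eq) / 3000)
        assert np.all(np.abs(occ - p_eq) < 4 * se)

    def test_relaxation_after_tension_step(self, params):
        """Occupancy after a step matches the two-state relaxation law."""
        gamma = 2.0
        hold = make_hold(gamma, 2.0)
        trajs = simulate_ensemble(params, hold, 3000, "fixed_closed", 19)
        k_tot = opening_rate(params, gamma) + closing_rate(params, gamma)
        p_eq = equilibrium_popen(params, gamma)
        grid = np.array([0.1, 0.3, 0.6, 1.0, 2.0])
        occ = mean_occupancy(trajs, grid)
        expected = p_eq + (0.0 - p_eq) * np.exp(-k_tot * grid)
        se = np.sqrt(np.maximum(expected * (1 - expected), 1e-4) / 3000)
        assert np.all(np.abs(occ - expected) < 4 * se)

    def test_single_trajectory_occupancy_is_step_function(self, params, fast_ramp):
        trajs = simulate_ensemble(params, fast_ramp, 1, "fixed_closed", 23)
        occ = mean_occupancy(trajs, np.linspace(0, 0.25, 100))
        assert set(np.unique(occ)) <= {0.0, 1.0}

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            mean_occupancy([], [0.0])
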