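"""Core dynamics: initial conditions, the synchronous stepper, absorption."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sirs1d import (
    S,
    I,
    R,
    SIRSParams,
    LatticeState,
    Trajectory,
    density,
    init_full,
    init_full_staggered,
    init_single_seed,
    init_uniform_random,
    run_until_absorbed,
    sync_step,
)
from ._reference import reference_run, reference_step
from .conftest import random_state


def params_for(N, lam=0.5, k=1, tau_I=2, tau_R=3, **kw):
    return SIRSParams(N=N, lam=lam, k=k, tau_I=tau_I, tau_R=tau_R, **kw)


class FixedDraws:
    """Feeds a predetermined uniform array to the stepper."""

    def __init__(self, u):
        self.u = u

    def random(self, n):
        assert n == len(self.u)
        return self.u


class TestParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"N": 0, "lam": 0.5},
            {"N": 10, "lam": -0.1},
            {"N": 10, "lam": 1.5},
            {"N": 10, "lam": 0.5, "k": 5},  # 2k >= N
            {"N": 10, "lam": 0.5, "tau_I": 0},
            {"N": 10, "lam": 0.5, "tau_R": 0},
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            SIRSParams(**kw)

    def test_study_defaults(self):
        p = SIRSParams(N=100, lam=0.1)
        assert (p.k, p.tau_I, p.tau_R) == (3, 7, 9)


class TestInits:
    @pytest.mark.parametrize("N,seed_site", [(11, 5), (1, 0), (4, 2)])
    def test_single_seed_at_centre(self, N, seed_site):
        p = params_for(N, k=1)
        st_ = init_single_seed(p)
        assert st_.comp[seed_site] == I
        assert np.count_nonzero(st_.comp == I) == 1
        assert st_.clock.sum() == 0 and st_.time == 0

    def test_uniform_random_exact_count(self):
        p = params_for(10_000, k=3, tau_I=7, tau_R=9)
        rng = np.random.default_rng(0)
        st_ = init_uniform_random(p, 0.1, rng)
        assert np.count_nonzero(st_.comp == I) == 1000

    @pytest.mark.parametrize("rho0", [0.0, 1.0])
    def test_uniform_random_degenerate(self, rho0):
        p = params_for(50)
        st_ = init_uniform_random(p, rho0, np.random.default_rng(1))
        assert density(st_) == rho0

    def test_uniform_random_count_over_draws(self):
        p = params_for(97)
        rng = np.random.default_rng(2)
        for _ in range(50):
            rho0 = rng.random()
            st_ = init_uniform_random(p, rho0, rng)
            assert np.count_nonzero(st_.comp == I) == round(rho0 * 97)

    def test_full_equals_uniform_at_one(self):
        p = params_for(37)
        a = init_full(p)
        b = init_uniform_random(p, 1.0, np.random.default_rng(3))
        assert np.array_equal(a.comp, b.comp)
        assert density(a) == 1.0

    def test_staggered_full_occupancy(self):
        p = SIRSParams(N=10_000, lam=0.1)
        st_ = init_full_staggered(p, np.random.default_rng(4))
        assert np.count_nonzero(st_.comp == S) == 0
        st_.validate(p)
        # expected active fraction tau_I/(tau_I+tau_R)
        assert abs(density(st_) - 7 / 16) < 0.02


class TestDensity:
    def test_extremes_and_single_seed(self):
        p = params_for(11, k=1)
        assert density(init_full(p)) == 1.0
        all_s = LatticeState(np.zeros(11, np.int8), np.zeros(11, np.int32))
        assert density(all_s) == 0.0
        assert density(init_single_seed(p)) == pytest.approx(1 / 11)


class TestSyncStep:
    def test_zero_infectivity_only_clocks_advance(self):
        p = params_for(50, lam=0.0, k=2, tau_I=3, tau_R=4)
        rng = np.random.default_rng(5)
        st0 = random_state(p, rng)
        st1 = sync_step(st0, p, rng)
        # no S site became infected
        assert not np.any((st0.comp == S) & (st1.comp == I))
        # I sites either aged or turned R, never S
        assert not np.any((st0.comp == I) & (st1.comp == S))

    def test_all_susceptible_is_fixed_point(self):
        p = params_for(30, lam=1.0, k=1)
        st_ = LatticeState(np.zeros(30, np.int8), np.zeros(30, np.int32))
        for _ in range(5):
            st_ = sync_step(st_, p, p.rng())
            assert np.count_nonzero(st_.comp) == 0

    def test_deterministic_front_one_step(self):
        p = params_for(11, lam=1.0, k=1)
        st_ = sync_step(init_single_seed(p), p, p.rng())
        assert set(np.flatnonzero(st_.comp == I)) == {4, 5, 6}

    def test_deterministic_front_advances_one_site_per_step(self):
        p = params_for(41, lam=1.0, k=1, tau_I=5, tau_R=6)
        st_ = init_single_seed(p)
        rng = p.rng()
        for t in range(1, 15):
            st_ = sync_step(st_, p, rng)
            active = np.flatnonzero(st_.comp == I)
            assert active.min() == 20 - t and active.max() == 20 + t

    def test_conservation_every_step(self):
        p = params_for(100, lam=0.3, k=3, tau_I=7, tau_R=9)
        rng = np.random.default_rng(6)
        st_ = random_state(p, rng)
        for _ in range(50):
            st_ = sync_step(st_, p, rng)
            assert sum(st_.counts()) == 100
            st_.validate(p)

    def test_matches_reference_on_random_states(self):
        """Vectorised and per-site steppers agree exactly on shared draws."""
        rng = np.random.default_rng(7)
        for trial in range(100):
            N = int(rng.integers(5, 40))
            k = int(rng.integers(1, max(2, (N - 1) // 2)))
            p = SIRSParams(
                N=N, lam=float(rng.random()), k=k,
                tau_I=int(rng.integers(1, 8)), tau_R=int(rng.integers(1, 10)),
            )
            st_ = random_state(p, rng)
            u = rng.random(N)
            got = sync_step(st_, p, FixedDraws(u))
            ref_comp, ref_clock = reference_step(
                list(st_.comp), list(st_.clock), list(u),
                p.lam, p.k, p.tau_I, p.tau_R,
            )
            assert list(got.comp) == ref_comp
            assert list(got.clock) == ref_clock

    def test_per_site_infection_frequencies_match_reference(self):
        """Empirical one-step infection frequencies agree between steppers."""
        p = params_for(7, lam=0.5, k=1, tau_I=2, tau_R=3)
        st0 = init_single_seed(p)
        n = 30_000
        rng = np.random.default_rng(8)
        freq_pkg = np.zeros(7)
        freq_ref = np.zeros(7)
        for _ in range(n):
            u = rng.random(7)
            st1 = sync_step(st0, p, FixedDraws(u))
            freq_pkg += st1.comp == I
            ref_comp, _ = reference_step(
                list(st0.comp), list(st0.clock), list(u), 0.5, 1, 2, 3
            )
            freq_ref += np.array(ref_comp) == I
        freq_pkg /= n
        freq_ref /= n
        se = np.sqrt(0.25 / n)
        assert np.all(np.abs(freq_pkg - freq_ref) <= 3 * se)
        # the seed's two neighbours are each infected with probability lam
        centre = 7 // 2
        for site in (centre - 1, centre + 1):
            assert abs(freq_pkg[site] - 0.5) <= 4 * se


class TestRunUntilAbsorbed:
    def test_worked_example_clears_at_step_11(self, fig_params):
        traj = run_until_absorbed(
            init_single_seed(fig_params), fig_params, fig_params.rng(),
            record_spacetime=True,
        )
        assert traj.clearance_step == 11
        assert traj.all_susceptible_at == 10
        assert not traj.survived
        assert np.count_nonzero(traj.spacetime[-1]) == 0

    def test_zero_infectivity_absorbs_within_one_cycle(self):
        p = params_for(60, lam=0.0, k=2, tau_I=4, tau_R=5, max_steps=100)
        rng = np.random.default_rng(9)
        traj = run_until_absorbed(random_state(p, rng), p, rng)
        assert traj.absorbed_at is not None
        assert traj.absorbed_at <= p.tau_I
        assert traj.all_susceptible_at <= p.tau_I + p.tau_R

    def test_deterministic_ring_matches_reference_run(self):
        p = params_for(31, lam=1.0, k=1, tau_I=2, tau_R=3, max_steps=200)
        traj = run_until_absorbed(init_single_seed(p), p, p.rng())
        comp = [S] * 31
        comp[15] = I
        ref_absorbed, ref_all_s = reference_run(
            comp, [0] * 31, np.random.default_rng(0), 1.0, 1, 2, 3, 200
        )
        assert traj.absorbed_at == ref_absorbed
        assert traj.all_susceptible_at == ref_all_s

    def test_absorbing_state_stays_absorbed(self):
        """Once the infected count is zero it is zero at all later steps."""
        p = params_for(40, lam=0.8, k=2, tau_I=2, tau_R=2, max_steps=500)
        rng = np.random.default_rng(10)
        st_ = random_state(p, rng)
        while st_.n_infected() > 0:
            st_ = sync_step(st_, p, rng)
        for _ in range(100):
            st_ = sync_step(st_, p, rng)
            assert st_.n_infected() == 0

    def test_rho_zero_after_absorption(self):
        p = params_for(30, lam=0.2, k=1, tau_I=2, tau_R=3, max_steps=300)
        rng = np.random.default_rng(11)
        traj = run_until_absorbed(init_single_seed(p), p, rng)
        if traj.absorbed_at is not None:
            assert np.all(traj.rho[traj.absorbed_at:] == 0)

    def test_max_steps_zero_is_degenerate_survival(self):
        p = params_for(20, lam=0.5, k=1, max_steps=0)
        traj = run_until_absorbed(init_single_seed(p), p, p.rng())
        assert traj.survived
        assert len(traj.rho) == 1

    def test_synchronised_full_lattice_is_transient_absorbing(self):
        """All-I with aligned clocks recovers en masse and dies in tau_I steps."""
        p = params_for(100, lam=0.9, k=3, tau_I=7, tau_R=9, max_steps=50)
        traj = run_until_absorbed(init_full(p), p, p.rng())
        assert traj.absorbed_at == p.tau_I
        assert traj.all_susceptible_at == p.tau_I + p.tau_R


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    n=st.integers(5, 60),
    lam=st.floats(0.0, 1.0),
    tau_i=st.integers(1, 6),
    tau_r=st.integers(1, 8),
    seed=st.integers(0, 2**31 - 1),
)
def test_conservation_and_clock_bounds_property(n, lam, tau_i, tau_r, seed):
    """Compartment counts sum to N and clocks respect their bounds."""
    k = min(2, (n - 1) // 2)
    if k < 1:
        return
    p = SIRSParams(N=n, lam=lam, k=k, tau_I=tau_i, tau_R=tau_r)
    rng = np.random.default_rng(seed)
    st_ = random_state(p, rng)
    for _ in range(20):
        st_ = sync_step(st_, p, rng)
        assert sum(st_.counts()) == n
        st_.validate(p)
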