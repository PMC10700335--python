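"""Synchronous SIRS dynamics on a one-dimensional periodic lattice.

The model lives on a ring of ``N`` sites, each connected to its ``k``
nearest neighbours on either side (degree ``2k``).  Every site is in one
of three compartments:

* ``S`` — susceptible,
* ``I`` — infected (active); infects each susceptible neighbour
  independently with probability ``lam`` per time step,
* ``R`` — refractory (immune, non-infectious).

All sites update simultaneously from the state at the current step:

1. A susceptible site with ``m >= 1`` infected neighbours becomes
   infected with probability ``1 - (1 - lam)**m`` (independent
   per-neighbour attempts).
2. An infected site stays infected for ``tau_I`` full steps, then turns
   refractory.
3. A refractory site stays refractory for ``tau_R`` full steps, then
   turns susceptible again.

The all-susceptible configuration is the stationary absorbing state; a
configuration with no infected site can never create one, so the
dynamics after the last infection is a deterministic clock run-out.

Random-number contract
----------------------
Each step consumes exactly one uniform variate per lattice site, in site
order; only susceptible sites with at least one infected neighbour
actually compare their variate against the infection probability.  This
fixed scheme makes the vectorised stepper reproducible and directly
comparable, draw for draw, with a plain per-site implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "S",
    "I",
    "R",
    "SIRSParams",
    "LatticeState",
    "Trajectory",
    "init_single_seed",
    "init_uniform_random",
    "init_full",
    "init_full_staggered",
    "sync_step",
    "run_until_absorbed",
    "density",
]

logger = logging.getLogger(__name__)

# Compartment codes, fixed package-wide (also the grayscale export order).
S: int = 0
I: int = 1  # noqa: E741 - the compartment really is called I
R: int = 2

COMPARTMENT_SYMBOLS = ("S", "I", "R")


@dataclass(frozen=True)
class SIRSParams:
    """Model constants and run controls for one simulation.

    Parameters
    ----------
    N : int
        Number of lattice sites on the ring.
    lam : float
        Per-neighbour, per-step infection probability ``λ`` in [0, 1].
    k : int
        Neighbours on *each side*; every site has degree ``2k``.
    tau_I : int
        Number of full steps a site spends infected.
    tau_R : int
        Number of full steps a site spends refractory.
    max_steps : int
        Cap on the number of synchronous updates per realization.
    seed : int, optional
        Master RNG seed; ``None`` draws fresh OS entropy.
    """

    N: int
    lam: float
    k: int = 3
    tau_I: int = 7
    tau_R: int = 9
    max_steps: int = 10_000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.N > 1 and 2 * self.k >= self.N:
            raise ValueError(
                f"neighbourhood must not wrap onto itself: need 2k < N, "
                f"got k={self.k}, N={self.N}"
            )
        if self.tau_I < 1:
            raise ValueError(f"tau_I must be >= 1, got {self.tau_I}")
        if self.tau_R < 1:
            raise ValueError(f"tau_R must be >= 1, got {self.tau_R}")
        if self.max_steps < 0:
            raise ValueError(f"max_steps must be >= 0, got {self.max_steps}")

    def rng(self) -> np.random.Generator:
        """A fresh generator seeded from ``seed``."""
        return np.random.default_rng(self.seed)


@dataclass
class LatticeState:
    """One lattice configuration: compartments, phase clocks and time.

    ``clock[i]`` counts the completed steps site ``i`` has spent in its
    current non-susceptible compartment (always 0 for S sites), so
    ``clock[i] < tau_I`` for infected and ``clock[i] < tau_R`` for
    refractory sites.
    """

    comp: np.ndarray  # int8, values in {S, I, R}
    clock: np.ndarray  # int32, phase clock per site
    time: int = 0

    def __post_init__(self) -> None:
        self.comp = np.asarray(self.comp, dtype=np.int8)
        self.clock = np.asarray(self.clock, dtype=np.int32)
        if self.comp.shape != self.clock.shape or self.comp.ndim != 1:
            raise ValueError("comp and clock must be 1-d arrays of equal length")

    @property
    def N(self) -> int:
        return self.comp.shape[0]

    def counts(self) -> tuple[int, int, int]:
        """(S, I, R) occupation numbers; they always sum to N."""
        c = np.bincount(self.comp, minlength=3)
        return int(c[S]), int(c[I]), int(c[R])

    def n_infected(self) -> int:
        return int(np.count_nonzero(self.comp == I))

    def copy(self) -> "LatticeState":
        return LatticeState(self.comp.copy(), self.clock.copy(), self.time)

    def validate(self, params: SIRSParams) -> None:
        """Raise if the configuration violates the model invariants."""
        if self.N != params.N:
            raise ValueError(f"state has {self.N} sites, params expect {params.N}")
        if not np.isin(self.comp, (S, I, R)).all():
            raise ValueError("compartment codes must be in {S, I, R}")
        if np.any(self.clock < 0):
            raise ValueError("clocks must be non-negative")
        if np.any(self.clock[self.comp == S] != 0):
            raise ValueError("susceptible sites must have clock 0")
        if np.any(self.clock[self.comp == I] >= params.tau_I):
            raise ValueError("infected clock must stay below tau_I")
        if np.any(self.clock[self.comp == R] >= params.tau_R):
            raise ValueError("refractory clock must stay below tau_R")


@dataclass
class Trajectory:
    """Outcome of one realization.

    Attributes
    ----------
    rho : np.ndarray
        Active density ``ρ(t)`` for every recorded step, starting with
        the initial configuration at internal time 0.
    absorbed_at : int or None
        First internal time with zero infected sites (the epidemic is
        over; refractory sites may still be running out their clocks).
        ``None`` if still active when the step cap was reached.
    all_susceptible_at : int or None
        First internal time at which every site is susceptible — the
        stationary absorbing state.
    survived : bool
        True when infected sites remain at ``max_steps``.
    spacetime : np.ndarray or None
        Optional (steps+1, N) compartment matrix, row 0 = initial state.
    """

    rho: np.ndarray
    absorbed_at: Optional[int]
    all_susceptible_at: Optional[int]
    survived: bool
    spacetime: Optional[np.ndarray] = None

    @property
    def clearance_step(self) -> Optional[int]:
        """Step at which the lattice is all-susceptible, counting the
        initial configuration as step 1 (the row index in a space-time
        diagram).  ``None`` if the run never cleared."""
        if self.all_susceptible_at is None:
            return None
        return self.all_susceptible_at + 1


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

def init_single_seed(params: SIRSParams) -> LatticeState:
    """All susceptible except one infected site at the lattice centre."""
    comp = np.full(params.N, S, dtype=np.int8)
    comp[params.N // 2] = I
    return LatticeState(comp, np.zeros(params.N, dtype=np.int32), 0)


def init_uniform_random(
    params: SIRSParams, rho0: float, rng: np.random.Generator
) -> LatticeState:
    """Exactly ``round(rho0 * N)`` infected sites, uniformly placed."""
    if not 0.0 <= rho0 <= 1.0:
        raise ValueError(f"rho0 must be in [0, 1], got {rho0}")
    n_seed = int(round(rho0 * params.N))
    comp = np.full(params.N, S, dtype=np.int8)
    if n_seed > 0:
        sites = rng.choice(params.N, size=n_seed, replace=False)
        comp[sites] = I
    return LatticeState(comp, np.zeros(params.N, dtype=np.int32), 0)


def init_full(params: SIRSParams) -> LatticeState:
    """Fully occupied lattice: every site infected with a fresh clock.

    With synchronised clocks this *is* the transient absorbing state:
    no susceptible site ever appears, the whole lattice turns refractory
    after ``tau_I`` steps and susceptible after ``tau_I + tau_R``.  For
    decay studies that need a sustained fully-active start, use
    :func:`init_full_staggered`.
    """
    comp = np.full(params.N, I, dtype=np.int8)
    return LatticeState(comp, np.zeros(params.N, dtype=np.int32), 0)


def init_full_staggered(
    params: SIRSParams, rng: np.random.Generator
) -> LatticeState:
    """Fully occupied lattice with random phases along the infection cycle.

    Every site carries a particle placed uniformly at random somewhere
    in its ``tau_I + tau_R``-step I→R cycle, so recoveries and returns
    to susceptibility are continuously staggered instead of happening in
    one synchronised wave.  Expected initial active density is
    ``tau_I / (tau_I + tau_R)``.  This is the non-degenerate
    fully-occupied start used for critical-decay measurements.
    """
    cycle = params.tau_I + params.tau_R
    phase = rng.integers(0, cycle, params.N)
    infected = phase < params.tau_I
    comp = np.where(infected, I, R).astype(np.int8)
    clock = np.where(infected, phase, phase - params.tau_I).astype(np.int32)
    return LatticeState(comp, clock, 0)


# ---------------------------------------------------------------------------
# the synchronous stepper
# ---------------------------------------------------------------------------

@njit(cache=True)
def _step_kernel(comp, clock, u, lam, k, tau_I, tau_R, out_comp, out_clock):  # pragma: no cover - jitted
    """One synchronous update; writes the successor into out_comp/out_clock.

    ``u`` holds one uniform variate per site; only susceptible sites
    with an infected neighbour consume theirs.
    """
    N = comp.shape[0]
    for i in range(N):
        c = comp[i]
        if c == 0:  # S
            m = 0
            for d in range(1, k + 1):
                j = i - d
                if j < 0:
                    j += N
                if comp[j] == 1:
                    m += 1
                j = i + d
                if j >= N:
                    j -= N
                if comp[j] == 1:
                    m += 1
            if m > 0 and u[i] < 1.0 - (1.0 - lam) ** m:
                out_comp[i] = 1
            else:
                out_comp[i] = 0
            out_clock[i] = 0
        elif c == 1:  # I
            if clock[i] == tau_I - 1:
                out_comp[i] = 2
                out_clock[i] = 0
            else:
                out_comp[i] = 1
                out_clock[i] = clock[i] + 1
        else:  # R
            if clock[i] == tau_R - 1:
                out_comp[i] = 0
                out_clock[i] = 0
            else:
                out_comp[i] = 2
                out_clock[i] = clock[i] + 1
    return out_comp, out_clock


def sync_step(
    state: LatticeState, params: SIRSParams, rng: np.random.Generator
) -> LatticeState:
    """Advance one synchronous step; returns a new :class:`LatticeState`.

    All transitions are computed from the state at the current time, so
    a site can never be infected and recover within the same step.
    """
    u = rng.random(state.N)
    out_comp = np.empty_like(state.comp)
    out_clock = np.empty_like(state.clock)
    _step_kernel(
        state.comp, state.clock, u,
        params.lam, params.k, params.tau_I, params.tau_R,
        out_comp, out_clock,
    )
    return LatticeState(out_comp, out_clock, state.time + 1)


def density(state: LatticeState) -> float:
    """Active density: fraction of infected sites."""
    return state.n_infected() / state.N


def run_until_absorbed(
    state: LatticeState,
    params: SIRSParams,
    rng: np.random.Generator,
    record_spacetime: bool = False,
) -> Trajectory:
    """Iterate the dynamics until the epidemic dies out or the step cap hits.

    The run continues past the last infected site until the lattice is
    all-susceptible (a deterministic clock run-out of at most ``tau_R``
    extra steps), so the trajectory covers the full approach to the
    stationary absorbing state.
    """
    comp = state.comp.copy()
    clock = state.clock.copy()
    t0 = state.time
    N = comp.shape[0]

    if params.max_steps == 0 and np.count_nonzero(comp == I) > 0:
        logger.warning(
            "max_steps=0 with an active initial state: no dynamics recorded"
        )

    rho = [np.count_nonzero(comp == I) / N]
    rows = [comp.copy()] if record_spacetime else None
    absorbed_at: Optional[int] = None
    all_s_at: Optional[int] = None
    if rho[0] == 0.0:
        absorbed_at = t0
        if np.count_nonzero(comp) == 0:
            all_s_at = t0

    buf_comp = np.empty_like(comp)
    buf_clock = np.empty_like(clock)
    t = t0
    while t - t0 < params.max_steps and all_s_at is None:
        u = rng.random(N)
        _step_kernel(
            comp, clock, u,
            params.lam, params.k, params.tau_I, params.tau_R,
            buf_comp, buf_clock,
        )
        comp, buf_comp = buf_comp, comp
        clock, buf_clock = buf_clock, clock
        t += 1
        n_inf = np.count_nonzero(comp == I)
        rho.append(n_inf / N)
        if rows is not None:
            rows.append(comp.copy())
        if n_inf == 0:
            if absorbed_at is None:
                absorbed_at = t
            if np.count_nonzero(comp) == 0:
                all_s_at = t

    return Trajectory(
        rho=np.asarray(rho),
        absorbed_at=absorbed_at,
        all_susceptible_at=all_s_at,
        survived=absorbed_at is None,
        spacetime=np.asarray(rows, dtype=np.int8) if rows is not None else None,
    )
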