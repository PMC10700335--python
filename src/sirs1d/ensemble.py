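"""Realization ensembles: order-parameter averages and trapped-run statistics.

An *ensemble* is a set of independent realizations of the automaton
sharing parameters and an initial-condition recipe but differing in
their random streams.  This module averages the active density over
such ensembles, computes steady-state values and fluctuation measures,
and classifies *trapped* configurations — realizations whose epidemic
dies within a single infection cycle, the signature of the
high-infectivity route into the absorbing state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import (
    SIRSParams,
    LatticeState,
    Trajectory,
    init_full,
    init_full_staggered,
    init_single_seed,
    init_uniform_random,
    run_until_absorbed,
)

__all__ = [
    "EnsembleSummary",
    "NoSurvivorsError",
    "trapped_cutoff",
    "classify_trapped",
    "run_ensemble",
    "dtco_curve",
    "steady_state_scan",
    "scan_frame",
]

logger = logging.getLogger(__name__)

#: initial-condition recipe: "single", "full", or an initial density in [0, 1]
InitSpec = Union[str, float]


class NoSurvivorsError(RuntimeError):
    """Raised when a surviving-run average is requested but every
    realization was absorbed before the step cap."""


def subseed(master: Optional[int], *key: int) -> int:
    """Counter-based child seed: independent of how many siblings exist
    or in which order they are drawn."""
    ss = np.random.SeedSequence(master, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def make_initial_state(
    params: SIRSParams, init: InitSpec, rng: np.random.Generator
) -> LatticeState:
    """Build the initial lattice from a recipe.

    ``"single"`` seeds one infected site at the centre, ``"full"``
    infects every site with synchronised clocks, ``"staggered"``
    occupies every site at a random phase of the infection cycle, and a
    float is the initial active density for a uniformly random
    placement of fresh infections.
    """
    if init == "single":
        return init_single_seed(params)
    if init == "full":
        return init_full(params)
    if init == "staggered":
        return init_full_staggered(params, rng)
    if isinstance(init, str):
        raise ValueError(f"unknown init spec {init!r}")
    return init_uniform_random(params, float(init), rng)


def trapped_cutoff(params: SIRSParams) -> int:
    """Duration of one full infection cycle, in time steps.

    Counts inclusively from the step at which a particle becomes
    infected through the step at which it is first susceptible again:
    ``tau_I`` infected steps, ``tau_R`` refractory steps, plus the
    return step — 17 for the default ``tau_I=7, tau_R=9``.  A
    realization absorbed within this window never completed a single
    infection generation.
    """
    return params.tau_I + params.tau_R + 1


def classify_trapped(traj: Trajectory, cutoff: int) -> bool:
    """True iff the epidemic died out within ``cutoff`` steps (inclusive)."""
    return traj.absorbed_at is not None and traj.absorbed_at <= cutoff


@dataclass
class EnsembleSummary:
    """Aggregates of one ensemble at fixed (λ, initial condition, N)."""

    lam: float
    init: InitSpec
    N: int
    reps: int
    rho_s_mean: float  #: steady-state density over the averaging set
    rho_mean_t: np.ndarray  #: per-step ensemble mean of ρ(t)
    rho_var: float  #: population variance of pooled survivor densities
    chi: float  #: order-parameter variance χ = N·Var(ρ), survivors only
    dtco: float  #: fraction of trapped configurations
    surviving: int  #: realizations still active at max_steps
    trapped: int
    cutoff: int  #: trapped-classification threshold (steps)
    discard: int
    window: int
    average_over: str

    @property
    def rho0(self) -> Optional[float]:
        """Initial density when the recipe is a random placement."""
        return float(self.init) if not isinstance(self.init, str) else None

    def to_row(self) -> dict:
        return {
            "lam": self.lam,
            "init": self.init,
            "N": self.N,
            "reps": self.reps,
            "rho_s": self.rho_s_mean,
            "rho_var": self.rho_var,
            "chi": self.chi,
            "dtco": self.dtco,
            "surviving": self.surviving,
            "trapped": self.trapped,
        }


def run_ensemble(
    params: SIRSParams,
    init: InitSpec,
    reps: int,
    discard: int = 0,
    average_over: str = "all",
    window: int = 1_000,
    seed: Optional[int] = None,
) -> EnsembleSummary:
    """Run ``reps`` independent realizations and aggregate them.

    Parameters
    ----------
    discard : int
        Transient steps excluded from the steady-state time average.
    average_over : {"all", "surviving"}
        Averaging set for ``rho_mean_t``/``rho_s_mean``.  With "all",
        absorbed realizations contribute zero density after absorption;
        with "surviving", only runs still active at ``max_steps`` enter
        (raises :class:`NoSurvivorsError` if there are none).
    window : int
        Length of the post-discard averaging window (clipped to the
        recorded trajectory length).
    seed : int, optional
        Master seed; realization ``i`` uses the counter-derived child
        ``subseed(seed, i)``, so results are reproducible and
        independent of execution order.

    Fluctuation measures (``rho_var``, ``chi``) always pool the
    per-step densities of *surviving* runs inside the window, the
    convention for locating pseudo-critical variance peaks; they are
    NaN when no run survives.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if average_over not in ("all", "surviving"):
        raise ValueError(f"average_over must be 'all' or 'surviving', got {average_over!r}")
    if seed is None:
        seed = params.seed

    T = params.max_steps + 1
    rho_mat = np.zeros((reps, T), dtype=np.float64)
    survived = np.zeros(reps, dtype=bool)
    cutoff = trapped_cutoff(params)
    trapped = 0
    for i in range(reps):
        rng = np.random.default_rng(subseed(seed, i))
        state = make_initial_state(params, init, rng)
        traj = run_until_absorbed(state, params, rng)
        rho_mat[i, : traj.rho.shape[0]] = traj.rho
        survived[i] = traj.survived
        if classify_trapped(traj, cutoff):
            trapped += 1

    n_surv = int(survived.sum())
    if average_over == "surviving" and n_surv == 0:
        raise NoSurvivorsError(
            f"no realization survived to max_steps={params.max_steps} "
            f"at lam={params.lam}, N={params.N}, init={init!r}"
        )
    sel = rho_mat[survived] if average_over == "surviving" else rho_mat
    rho_mean_t = sel.mean(axis=0)

    lo = min(discard, T - 1)
    hi = min(lo + window, T)
    rho_s_mean = float(rho_mean_t[lo:hi].mean())

    if n_surv > 0:
        samples = rho_mat[survived, lo:hi].ravel()
        rho_var = float(np.var(samples))
    else:
        rho_var = float("nan")
    chi = params.N * rho_var

    return EnsembleSummary(
        lam=params.lam,
        init=init,
        N=params.N,
        reps=reps,
        rho_s_mean=rho_s_mean,
        rho_mean_t=rho_mean_t,
        rho_var=rho_var,
        chi=chi,
        dtco=trapped / reps,
        surviving=n_surv,
        trapped=trapped,
        cutoff=cutoff,
        discard=lo,
        window=hi - lo,
        average_over=average_over,
    )


def dtco_curve(
    params: SIRSParams,
    rho0_grid: Sequence[float],
    reps: int,
    seed: Optional[int] = None,
) -> list[tuple[float, float]]:
    """Density of trapped configurations versus initial density.

    For each initial density the fraction of ``reps`` realizations
    absorbed within one infection cycle.  Only ``cutoff + 1`` steps are
    simulated per realization: any run still active then has, by
    definition, escaped the trapped window.
    """
    if len(rho0_grid) == 0:
        raise ValueError("rho0_grid must be nonempty")
    if seed is None:
        seed = params.seed
    cutoff = trapped_cutoff(params)
    short = replace(params, max_steps=cutoff + 1)
    out: list[tuple[float, float]] = []
    for j, rho0 in enumerate(rho0_grid):
        trapped = 0
        for i in range(reps):
            rng = np.random.default_rng(subseed(seed, j, i))
            state = make_initial_state(short, float(rho0), rng)
            traj = run_until_absorbed(state, short, rng)
            if classify_trapped(traj, cutoff):
                trapped += 1
        out.append((float(rho0), trapped / reps))
    return out


def steady_state_scan(
    params: SIRSParams,
    lam_grid: Sequence[float],
    init: InitSpec,
    reps: int,
    discard: int,
    average_over: str = "all",
    window: int = 1_000,
    seed: Optional[int] = None,
) -> list[EnsembleSummary]:
    """Steady-state density across an ascending λ grid.

    One ensemble per λ, each on an independent counter-derived seed.
    Sweeping λ across both thresholds traces the phase diagram: zero
    density below the low threshold, an active plateau between the two,
    and a collapse above the high one.
    """
    grid = list(lam_grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("lam_grid must be sorted ascending")
    if seed is None:
        seed = params.seed
    summaries = []
    for j, lam in enumerate(grid):
        p = replace(params, lam=float(lam))
        summaries.append(
            run_ensemble(
                p, init, reps,
                discard=discard, average_over=average_over,
                window=window, seed=subseed(seed, 1_000_003, j),
            )
        )
        logger.info(
            "scan lam=%.4f rho_s=%.5f surviving=%d/%d",
            lam, summaries[-1].rho_s_mean, summaries[-1].surviving, reps,
        )
    return summaries


def scan_frame(summaries: Iterable[EnsembleSummary]) -> pd.DataFrame:
    """Tabulate ensemble summaries, one row per ensemble."""
    return pd.DataFrame([s.to_row() for s in summaries])
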