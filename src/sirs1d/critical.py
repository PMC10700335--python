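"""Critical points, exponents, quasistationary histograms and finite-size scaling.

Two very different transitions bracket the active phase of the
automaton.  At the low-infectivity threshold the transition is
continuous and directed-percolation-like, characterised by

* the order-parameter exponent ``beta``:  rho_s ~ (lam - lam_c)**beta
  just above threshold, and
* the decay exponent ``delta``:  rho(t) ~ t**(-delta) at threshold when
  started from a fully occupied lattice

(the (1+1)-dimensional directed-percolation values are beta ≈ 0.276 and
delta ≈ 0.1595).  At the high-infectivity threshold no power laws
survive; the transition is located instead through the peak of the
order-parameter variance chi = N(<rho²> - <rho>²) over surviving runs,
whose position lam_N drifts with system size as
``lam_N = lam_c2 + a / N``, and its discontinuous character shows up as
bimodality of the quasistationary cell-occupancy histogram.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .ensemble import make_initial_state, subseed
from .model import I, SIRSParams, sync_step

__all__ = [
    "PowerLawFit",
    "CellHistogram",
    "FSSResult",
    "fit_beta",
    "fit_delta",
    "cell_histogram",
    "count_modes",
    "variance_chi",
    "locate_pseudo_critical",
    "extrapolate_lambda_c2",
    "estimate_lambda_c1",
    "refine_lambda_c1_powerlaw",
]

logger = logging.getLogger(__name__)

MIN_FIT_POINTS = 4


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares log-log fit ``y = amplitude * x**exponent``."""

    exponent: float
    amplitude: float
    stderr: float
    r2: float
    window: str
    npoints: int


@dataclass(frozen=True)
class CellHistogram:
    """Quasistationary occupancy counts of a fixed observation window.

    ``counts[n]`` is the number of samples in which exactly ``n`` of the
    ``window_size`` central sites were infected.
    """

    window_size: int
    counts: np.ndarray
    lam: float
    n_samples: int


@dataclass(frozen=True)
class FSSResult:
    """Finite-size extrapolation ``lam_N = lambda_c2 + slope_a / N``."""

    points: tuple[tuple[int, float], ...]
    lambda_c2: float
    slope_a: float
    stderr: float


def _loglog_fit(x: np.ndarray, y: np.ndarray, window: str) -> PowerLawFit:
    res = stats.linregress(np.log(x), np.log(y))
    return PowerLawFit(
        exponent=float(res.slope),
        amplitude=float(np.exp(res.intercept)),
        stderr=float(res.stderr),
        r2=float(res.rvalue**2),
        window=window,
        npoints=len(x),
    )


def fit_beta(
    scan: Sequence[tuple[float, float]],
    lam_c1: float,
    window: tuple[float, float] = (0.0, 0.05),
) -> PowerLawFit:
    """Order-parameter exponent from steady states above the threshold.

    Fits ``log(rho_s)`` against ``log(lam - lam_c1)`` over the points
    whose distance to the threshold falls in ``window``.

    Parameters
    ----------
    scan : sequence of (lam, rho_s)
        Steady-state densities; points at or below ``lam_c1`` or with
        non-positive density are ignored.
    """
    pts = [
        (lam - lam_c1, rho)
        for lam, rho in scan
        if lam > lam_c1 and rho > 0 and window[0] < lam - lam_c1 <= window[1]
    ]
    if len(pts) < MIN_FIT_POINTS:
        raise ValueError(
            f"need at least {MIN_FIT_POINTS} usable points above lam_c1, got {len(pts)}"
        )
    d, r = map(np.asarray, zip(*pts))
    return _loglog_fit(d, r, f"lam-lam_c1 in ({window[0]}, {window[1]}]")


def fit_delta(
    rho_t: Sequence[tuple[float, float]],
    t_window: tuple[float, float] = (1e2, 1e4),
) -> PowerLawFit:
    """Critical decay exponent from a density-versus-time curve.

    Fits ``log(rho)`` against ``log(t)`` over ``t_window`` and returns
    the *positive* decay exponent delta = -slope; a constant density
    therefore yields delta = 0.
    """
    pts = [
        (t, rho)
        for t, rho in rho_t
        if t >= max(t_window[0], 1) and t <= t_window[1] and rho > 0
    ]
    if len(pts) < MIN_FIT_POINTS:
        raise ValueError(
            f"need at least {MIN_FIT_POINTS} usable points in the time window, got {len(pts)}"
        )
    t, r = map(np.asarray, zip(*pts))
    fit = _loglog_fit(t, r, f"t in [{t_window[0]:g}, {t_window[1]:g}]")
    return PowerLawFit(
        exponent=-fit.exponent,
        amplitude=fit.amplitude,
        stderr=fit.stderr,
        r2=fit.r2,
        window=fit.window,
        npoints=fit.npoints,
    )


def cell_histogram(
    params: SIRSParams,
    lam: float,
    window_size: int,
    reps: int = 20,
    discard: int = 1_000,
    interval: int = 1,
    init: float | str = 0.1,
    seed: Optional[int] = None,
) -> CellHistogram:
    """Quasistationary occupancy histogram of a central cell.

    Runs ``reps`` realizations at infectivity ``lam``; after the
    ``discard`` transient, the number of infected sites inside the
    ``window_size`` central sites is recorded every ``interval`` steps
    for as long as the realization stays globally active (sampling is
    conditioned on survival, the quasistationary convention).  Near a
    continuous transition the histogram has a single peak; near the
    discontinuous one it is bimodal.
    """
    if window_size > params.N:
        raise ValueError("window_size must not exceed the lattice size")
    if seed is None:
        seed = params.seed
    p = replace(params, lam=float(lam))
    lo = (params.N - window_size) // 2
    hi = lo + window_size
    counts = np.zeros(window_size + 1, dtype=np.int64)
    n_samples = 0
    for i in range(reps):
        rng = np.random.default_rng(subseed(seed, i))
        state = make_initial_state(p, init, rng)
        alive = True
        for t in range(1, p.max_steps + 1):
            state = sync_step(state, p, rng)
            if state.n_infected() == 0:
                alive = False
                break
            if t > discard and (t - discard) % interval == 0:
                n = int(np.count_nonzero(state.comp[lo:hi] == I))
                counts[n] += 1
                n_samples += 1
        if not alive and state.time <= discard:
            logger.debug("realization %d absorbed in the transient (t=%d)", i, state.time)
    if n_samples == 0:
        raise RuntimeError(
            f"every realization was absorbed before the discard window at lam={lam}"
        )
    return CellHistogram(
        window_size=window_size, counts=counts, lam=float(lam), n_samples=n_samples
    )


def count_modes(
    hist: CellHistogram,
    smoothing: int = 2,
    separation: float = 0.5,
    floor: float = 0.003,
) -> int:
    """Number of well-separated modes of the smoothed occupancy histogram.

    The counts are smoothed by a moving average of half-width
    ``smoothing`` (edge-padded) and local maxima are located (a flat
    plateau counts once; a peak on either boundary — e.g. a point mass
    at zero occupancy — counts).  A maximum qualifies as a *mode* only
    if it is well separated from the rest of the distribution: its
    prominence must reach ``separation`` times its height, i.e. with
    the default 0.5 the valley splitting it off must drop to at most
    half the peak.  This peak-to-valley criterion is what
    distinguishes genuine phase coexistence (empty and dense phases
    with a deep gap between them, the discontinuous-transition
    signature) from the shallow wiggles and finite-window
    zero-occupancy excursions that decorate a single-phase histogram.
    Peaks holding less than ``floor`` of the total sample mass (peak
    height below ``floor`` times the total count) are ignored outright
    — they are sparse-tail sampling noise, however well separated.  At
    least 1 is returned for a nonempty histogram.
    """
    c = np.asarray(hist.counts, dtype=float)
    if c.sum() == 0:
        raise ValueError("histogram is empty")
    if smoothing > 0:
        w = 2 * smoothing + 1
        padded = np.pad(c, smoothing, mode="edge")
        c = np.convolve(padded, np.ones(w) / w, mode="valid")
    from scipy.signal import find_peaks

    # pad below the data range so boundary maxima are detectable
    padded = np.concatenate(([c.min() - 1.0], c, [c.min() - 1.0]))
    peaks, props = find_peaks(padded, prominence=1e-12)
    heights = padded[peaks]
    total = float(np.asarray(hist.counts).sum())
    qualified = (props["prominences"] >= separation * heights) & (
        heights >= floor * total
    )
    return max(int(qualified.sum()), 1)


def variance_chi(rho_samples: Sequence[float], N: int) -> float:
    """Order-parameter variance ``chi = N * (<rho²> - <rho>²)``.

    ``rho_samples`` are per-step densities of surviving configurations;
    the population variance is used.
    """
    samples = np.asarray(rho_samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 density samples")
    return float(N * np.var(samples))


def locate_pseudo_critical(chi_curve: Sequence[tuple[float, float]]) -> float:
    """Abscissa of the variance peak, the pseudo-critical point lam_N.

    Interpolates a parabola through the grid maximum and its two
    neighbours.  When the maximum sits on the grid boundary no parabola
    is defined; the boundary value is returned with a warning.
    """
    if len(chi_curve) < 5:
        raise ValueError("need at least 5 grid points spanning the peak")
    lam, chi = map(np.asarray, zip(*sorted(chi_curve)))
    i = int(np.nanargmax(chi))
    if i == 0 or i == len(lam) - 1:
        warnings.warn(
            f"variance maximum at the grid boundary lam={lam[i]:.5g}; "
            "widen the grid for a reliable peak",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(lam[i])
    x0, x1, x2 = lam[i - 1 : i + 2]
    y0, y1, y2 = chi[i - 1 : i + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # degenerate (flat or upward) triplet: fall back to grid argmax
        return float(lam[i])
    return float(-b / (2 * a))


def extrapolate_lambda_c2(points: Sequence[tuple[int, float]]) -> FSSResult:
    """Infinite-size threshold from pseudo-critical points.

    Ordinary least squares of ``lam_N`` on ``1/N``; the intercept is the
    infinite-size transition point ``lambda_c2`` and the slope the
    finite-size amplitude ``a``.
    """
    pts = sorted((int(n), float(l)) for n, l in points)
    sizes = {n for n, _ in pts}
    if len(sizes) < 3:
        raise ValueError("need at least 3 distinct system sizes")
    x = np.array([1.0 / n for n, _ in pts])
    y = np.array([l for _, l in pts])
    res = stats.linregress(x, y)
    return FSSResult(
        points=tuple(pts),
        lambda_c2=float(res.intercept),
        slope_a=float(res.slope),
        stderr=float(res.intercept_stderr),
    )


def estimate_lambda_c1(
    scan: Sequence[tuple[float, float]],
    zero_tol: float = 1e-4,
) -> float:
    """Bracket the low-infectivity onset from a steady-state scan.

    Returns the midpoint between the largest λ whose steady density is
    indistinguishable from zero (``rho_s <= zero_tol``) and the smallest
    λ with every later density positive.  The scan must actually
    bracket the onset; resolution is limited by the grid spacing.
    """
    pts = sorted(scan)
    rho = np.array([r for _, r in pts])
    lam = np.array([l for l, _ in pts])
    active = rho > zero_tol
    if not active.any():
        raise ValueError("scan never becomes active: no bracket for the onset")
    # first index from which the scan stays active
    first_active = len(active) - 1
    while first_active > 0 and active[first_active - 1]:
        first_active -= 1
    if first_active == 0:
        raise ValueError("scan is active at its lower end: no bracket for the onset")
    return float(0.5 * (lam[first_active - 1] + lam[first_active]))


def refine_lambda_c1_powerlaw(
    scan: Sequence[tuple[float, float]],
    candidates: Sequence[float],
    window: tuple[float, float] = (0.0, 0.05),
) -> tuple[float, PowerLawFit]:
    """Pick the threshold that maximises log-log linearity of the beta fit.

    For each candidate threshold the steady-state scan is refit as a
    power law in ``lam - candidate``; the candidate with the highest R²
    wins.  This is the standard 'best power law' refinement used when a
    continuous transition point must be located to sub-grid precision.
    """
    best: tuple[float, PowerLawFit] | None = None
    for c in candidates:
        try:
            fit = fit_beta(scan, c, window=window)
        except ValueError:
            continue
        if best is None or fit.r2 > best[1].r2:
            best = (float(c), fit)
    if best is None:
        raise ValueError("no candidate threshold admits a power-law fit")
    return best
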