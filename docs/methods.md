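# Methods

## Model

`sirs1d` simulates a stochastic cellular automaton for epidemic spread on a
ring of `N` sites with periodic boundaries, each site coupled to its `k`
nearest neighbours on either side (degree `2k`, default `k = 3`).  Sites are
susceptible (S), infected (I) or refractory (R) and all update synchronously
from the state at the current step:

* an S site with `m ≥ 1` infected neighbours becomes I with probability
  `1 − (1 − λ)^m` — each infected neighbour attempts transmission
  independently with probability `λ` per step;
* an I site remains infected for exactly `τ_I` full steps, then turns R;
* an R site remains refractory for exactly `τ_R` full steps, then turns S.

Defaults are the study conditions `τ_I = 7`, `τ_R = 9`.  Because all
transitions are computed from the old state, a site can never be infected
and recover within one step.  The random-number contract is fixed
project-wide: one uniform variate per site per step, consumed in site order,
with an S site comparing its variate against the combined probability
`1 − (1 − λ)^m`.  A plain per-site stepper in the test suite consumes draws
identically and must agree state-for-state with the vectorised kernel.

With `τ_R > τ_I` the model has two absorbing routes.  The all-S state is
stationary and absorbing.  The all-I state with synchronised clocks is a
*transient* absorbing state: no susceptible site remains, the whole lattice
turns refractory after `τ_I` steps and drains to all-S.  The active phase
lives between two thresholds `λ_c1 < λ < λ_c2`: below `λ_c1` transmission
cannot sustain itself; above `λ_c2` the infection sweeps the lattice so fast
that it synchronises itself into the transient absorbing state.

### Step counting

Internal time starts at 0 with the initial configuration.  Space-time
diagrams count rows from 1 (`clearance_step = all_susceptible_at + 1`), so
the 11-site worked example (`k = 1`, `λ = 1`, `τ_I = 2`, `τ_R = 3`, single
central seed) reaches all-S at diagram row 11.  `absorbed_at` is the first
internal time with zero infected sites; refractory clocks may still be
running out at that point.

### Initial conditions

* `single` — one infected site at `⌊N/2⌋`;
* density `ρ(0)` — exactly `round(ρ0·N)` infected sites, uniformly placed,
  all with fresh clocks;
* `full` — every site infected with synchronised clocks.  This is the
  transient absorbing state itself and dies in `τ_I` steps, which is the
  physically correct behaviour of the model;
* `staggered` — every site occupied at a uniformly random phase of the
  `τ_I + τ_R` infection cycle (expected active fraction `τ_I/(τ_I+τ_R)`).
  This is the fully-occupied start used for critical-decay measurements:
  it is the unique way to begin with a macroscopically occupied lattice
  whose recoveries are not synchronised into immediate global death.

## Ensembles

Realization `i` of an ensemble uses the counter-derived child seed
`SeedSequence(master, spawn_key=(i,))`, so every result is reproducible from
its parameter set plus one integer and independent of execution order.
Ensemble averages of `ρ(t)` are taken either over all runs (absorbed runs
contributing zero — the convention that makes the strong initial-condition
dependence near `λ_c2` visible) or over surviving runs only (the
quasistationary convention used for fluctuation measures).  Steady-state
densities are time averages of the ensemble mean over a post-discard window
(default 10³ steps).

A **trapped configuration** is a realization absorbed within one full
infection cycle, counted inclusively from the infection step through the
first return to S: `τ_I + τ_R + 1` steps, i.e. 17 for the default timers
(verified against a single-particle cycle oracle; the inclusive count is
what makes a (7, 9) cycle span 17 steps rather than 16).  The
trapped-configuration density (DTCO) versus `ρ(0)` only needs `cutoff + 1`
simulated steps per realization.

## Lower threshold and directed-percolation exponents

The transition at `λ_c1` is continuous; its exponents are measured in three
stages:

1. **Bracketing.**  A steady-state scan (`N = 2000`, 10⁴ steps, discard
   8·10³, 10 realizations per point, `ρ(0) = 0.1`) on a 0.002-spaced grid
   brackets the onset as the midpoint between the last statistically-zero
   and first clearly active grid point.  Finite-time activity just below
   threshold biases this bracket slightly low, which the next stage removes.
2. **Decay-shape refinement.**  From the phase-staggered fully occupied
   lattice at `N = 10⁴`, the averaged `ρ(t)` at the critical point is a pure
   power law `t^(−δ)`; off criticality the log-log curve bends — steepening
   below threshold, flattening above.  Candidate thresholds on a 0.001 grid
   above the bracket are scored by the *signed* curvature: the difference
   between the fitted decay slopes over `t ∈ [10², 10³]` and
   `t ∈ [10³, 10⁴]`.  The sign is far more noise-tolerant than maximising
   fit R², because a steep subcritical decay is also nearly straight on a
   log-log plot.  The zero crossing is located in two stages — a coarse
   pass on the 0.001 grid (16 realizations per candidate, `t ≤ 10⁴`),
   then a fine pass on a 0.0005 grid extending *upward* from the coarse
   crossing with trajectories extended to `t = 3·10⁴` (32 realizations
   per candidate, crossing by least squares, clipped to the fine grid).
   The fine pass buys two things: resolution (curvature differences
   between neighbouring thresholds are comparable to the coarse-pass
   noise, and the exponent moves by ≈0.05 per 0.001 of threshold error)
   and bias removal — over a finite window, critical corrections to
   scaling mimic a gentle flattening, so the short-window crossing sits
   ≈0.0003 *below* the true threshold; tripling the window removes most
   of this, and the upward-pointing fine grid is what lets the correction
   act instead of being clipped away.  The decay
   exponent δ is then refit over the stated window `t ∈ [10², 10⁴]` from
   a fresh 100-realization ensemble at the refined threshold.
   In this implementation the threshold lands near λ ≈ 0.093 and δ ≈ 0.16,
   consistent with (1+1)-dimensional directed percolation (δ ≈ 0.1595).
3. **Order-parameter exponent.**  Steady states are simulated at six
   distances `λ − λ_c1 ∈ [0.002, 0.013]` (`N = 5·10³`, 50 realizations,
   discard 10⁴, surviving-run averages).  The narrow fit window is
   deliberate: measured effective slopes fall towards ~0.15 for
   `λ − λ_c1 ≳ 0.015` (corrections to scaling), so the asymptotic exponent
   is visible only close to threshold.  The fitted slope is very sensitive
   to the assumed threshold (±0.0005 in `λ_c1` moves β by ≈0.05), so the
   fit uses the decay-refined threshold from stage 2 — the sharpest
   estimator available.  An alternative best-power-law refinement
   (re-picking the threshold on a 0.00025 grid to maximise fit R²) is
   implemented and selectable, but it is not the default: the
   slowest-equilibrating points closest to threshold carry a small upward
   bias that makes slightly-too-high thresholds look straighter, so the R²
   pick drifts upward and systematically flattens β.  With the stage-2
   threshold β comes out near 0.25 ± 0.03, consistent with the
   directed-percolation value 0.276.

## Upper threshold

Near `λ_c2` no power laws exist; the transition is located through
fluctuations.  For each size `N ∈ {500, 1000, 2000, 4000}` (200, 130, 85
and 60 realizations respectively) the order-parameter variance
`χ = N(⟨ρ²⟩ − ⟨ρ⟩²)` is computed from the pooled per-step densities of
surviving runs (`ρ(0) = 0.1`, 3·10³ steps, discard half) on a 0.005-spaced
λ grid that tracks the upward-drifting peak (0.16–0.22 for the two smaller
sizes, 0.18–0.24 for the larger).  Grid points with fewer than 8 survivors
are dropped — a variance estimate from a handful of runs is
noise-dominated.  Each peak position `λ_N` is located by a three-point
parabolic interpolation through the grid maximum, and the infinite-size
threshold is the intercept of an ordinary least-squares fit of `λ_N`
against `1/N`.  At these desk-scale sizes the peaks sit at
λ_N ≈ 0.18–0.215 and the intercept lands near 0.21–0.23; the peak is broad
and the extrapolation inherits a ±0.01 seed-to-seed scatter.

The discontinuous character shows up independently in the quasistationary
cell-occupancy histogram: the infected count in a 100-site central cell of
an `N = 10³` lattice, sampled each step while the realization is globally
active, after a 10³-step transient.  Near `λ_c1` the histogram has a single
interior peak; at `λ ≥ 0.15` it splits into a locally-empty mode and a dense
mode separated by a deep valley.  `count_modes` reports the number of
*well-separated* modes: after a moving-average smoothing (half-width 2
bins), a maximum counts only if its prominence reaches half its height
(peak-to-valley ratio ≥ 2) and its height reaches 5 % of the histogram
maximum.  Raw local-maximum counting is hopelessly noise-sensitive; the
separation criterion is exactly the phase-coexistence signature the
histogram is meant to detect.

## Known limitations

* The trapped-configuration analysis reproduces the qualitative picture —
  DTCO is monotone in `ρ(0)` and in λ — but in this implementation rare
  late-infection chains ("stragglers" that are infected many steps after
  the main sweep and bridge the refractory gap) keep a macroscopic survival
  probability up to `ρ(0) ≈ 0.85` at `λ = 0.16`, `N = 10⁴`.  The survival
  threshold in `ρ(0)` is therefore protocol-sensitive and much higher than
  a sweep-only argument suggests; it also varies between seeds because it
  is decided by rare events (~per-mille per-run probabilities at the top of
  the grid).
* Pseudo-critical peaks `λ_N` are broad and their location depends on the
  observation window (longer windows shift them modestly upward); the
  `1/N` extrapolation from sizes ≤ 4000 should be read with its ±0.01–0.02
  uncertainty.
* The simulator supports `τ_I ≥ τ_R` (single-threshold regime) but none of
  the analysis pipelines are calibrated for it.
* All tests and the acceptance pipeline run at desk scale (tens to a few
  hundred realizations, lattices ≤ 10⁴); these sizes were chosen as the
  smallest at which the scaling windows above are clean.
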