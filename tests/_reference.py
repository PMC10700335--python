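"""Independent per-site reference implementation of the SIRS update.

Deliberately plain: scalar loops, explicit neighbour walks, no numpy
vectorisation and no shared code with the package stepper.  Both
steppers consume the same uniform-variate array (one draw per site, in
site order), so given identical draws they must produce identical
states.
"""

from __future__ import annotations

S, I, R = 0, 1, 2


def reference_step(comp, clock, u, lam, k, tau_I, tau_R):
    """One synchronous update computed site by site from the old state.

    ``comp``/``clock`` are sequences of ints; returns two new lists.
    """
    N = len(comp)
    new_comp = [0] * N
    new_clock = [0] * N
    for i in range(N):
        if comp[i] == S:
            m = 0
            for d in range(1, k + 1):
                if comp[(i - d) % N] == I:
                    m += 1
                if comp[(i + d) % N] == I:
                    m += 1
            p_infect = 1.0 - (1.0 - lam) ** m
            if m > 0 and u[i] < p_infect:
                new_comp[i] = I
            else:
                new_comp[i] = S
        elif comp[i] == I:
            if clock[i] == tau_I - 1:
                new_comp[i] = R
            else:
                new_comp[i] = I
                new_clock[i] = clock[i] + 1
        else:
            if clock[i] == tau_R - 1:
                new_comp[i] = S
            else:
                new_comp[i] = R
                new_clock[i] = clock[i] + 1
    return new_comp, new_clock


def reference_run(comp, clock, rng, lam, k, tau_I, tau_R, max_steps):
    """Iterate the reference step until no infected site remains.

    Returns (first time with zero infected, first time all-susceptible),
    either being None if not reached within ``max_steps``.
    """
    comp, clock = list(comp), list(clock)
    absorbed_at = None
    all_s_at = None
    if I not in comp:
        absorbed_at = 0
        if R not in comp:
            all_s_at = 0
    t = 0
    while t < max_steps and all_s_at is None:
        u = [rng.random() for _ in comp]
        comp, clock = reference_step(comp, clock, u, lam, k, tau_I, tau_R)
        t += 1
        if I not in comp:
            if absorbed_at is None:
                absorbed_at = t
            if R not in comp:
                all_s_at = t
    return absorbed_at, all_s_at


def single_particle_cycle_length(tau_I, tau_R):
    """Steps one isolated particle spends from infection back to S, inclusive.

    Simulates one site with no neighbours at lam=0: infected at step 1,
    counted through the step at which it is first susceptible again.
    """
    comp, clock = [I], [0]
    steps = 1  # the infection step itself
    while comp[0] != S:
        comp, clock = reference_step(comp, clock, [1.0], 0.0, 0, tau_I, tau_R)
        steps += 1
    return steps
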