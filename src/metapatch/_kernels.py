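"""Numba-compiled inner loops of the stochastic lattice model.

Site states are encoded as uint8: 0 vacant, 1 competitor, 2 colonizer,
3 mixed.  All kernels take an explicit ``numpy.random.Generator`` so runs
are reproducible from a single seed.  The single-attempt kernel
:func:`attempt_update` is the sole definition of the transition rules; the
sweep and trajectory drivers below only iterate it.
"""

from __future__ import annotations

import numpy as np
from numba import njit

VACANT = np.uint8(0)
COMPETITOR = np.uint8(1)
COLONIZER = np.uint8(2)
MIXED = np.uint8(3)

MOORE = 0
VON_NEUMANN = 1


@njit(cache=True, inline="always")
def _neighbor_counts(grid, i, j, r, neighborhood):
    """Counts of singly occupied competitor / colonizer neighbors.

    Chebyshev ball of radius r (Moore) or Manhattan ball (von Neumann),
    excluding the focal site, with periodic wrap.  Mixed sites count as
    neither: while locked in interference they emit no colonizers.
    """
    h, w = grid.shape
    n_comp = 0
    n_col = 0
    n_tot = 0
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            if di == 0 and dj == 0:
                continue
            if neighborhood == VON_NEUMANN and abs(di) + abs(dj) > r:
                continue
            n_tot += 1
            v = grid[(i + di) % h, (j + dj) % w]
            if v == COMPETITOR:
                n_comp += 1
            elif v == COLONIZER:
                n_col += 1
    return n_comp, n_col, n_tot


@njit(cache=True)
def attempt_update(grid, i, j, beta_comp, beta_col, gamma, delta, eta, r,
                   neighborhood, lock_resolution, mixed_mortality, shield,
                   rng):
    """One random-sequential update attempt at site (i, j), in place.

    Vacant site: each species fires with probability beta * f (f = fraction
    of the neighborhood singly occupied by it); simultaneous fires are
    resolved by a scramble lottery proportional to the firing weights.
    Singly occupied site: dies with probability delta, otherwise is invaded
    to the mixed state with probability gamma * beta_other * f_other.
    Mixed site: resolves the interference lottery with probability
    ``lock_resolution``; the competitor wins with probability eta.

    Reconstruction knobs (defaults reproduce the baseline kernel):
    ``lock_resolution`` < 1 lengthens the interference lock;
    ``mixed_mortality`` lets locked sites die like singles; ``shield``
    applies the priority-effect damping gamma only to the competitor's
    cross-colonization into colonizer-held sites (the colonizer invades at
    full rate), mirroring colonizer-specific corridor blockage.
    """
    s = grid[i, j]
    if s == VACANT:
        n_comp, n_col, n_tot = _neighbor_counts(grid, i, j, r, neighborhood)
        if n_comp == 0 and n_col == 0:
            return
        p_comp = beta_comp * n_comp / n_tot
        p_col = beta_col * n_col / n_tot
        fire_comp = rng.random() < p_comp
        fire_col = rng.random() < p_col
        if fire_comp and fire_col:
            if rng.random() < p_comp / (p_comp + p_col):
                grid[i, j] = COMPETITOR
            else:
                grid[i, j] = COLONIZER
        elif fire_comp:
            grid[i, j] = COMPETITOR
        elif fire_col:
            grid[i, j] = COLONIZER
    elif s == MIXED:
        if mixed_mortality and rng.random() < delta:
            grid[i, j] = VACANT
        elif rng.random() < lock_resolution:
            if rng.random() < eta:
                grid[i, j] = COMPETITOR
            else:
                grid[i, j] = COLONIZER
    else:
        if rng.random() < delta:
            grid[i, j] = VACANT
            return
        n_comp, n_col, n_tot = _neighbor_counts(grid, i, j, r, neighborhood)
        if s == COMPETITOR:
            g = 1.0 if shield else gamma
            p_inv = g * beta_col * n_col / n_tot
        else:
            p_inv = gamma * beta_comp * n_comp / n_tot
        if p_inv > 0.0 and rng.random() < p_inv:
            grid[i, j] = MIXED


@njit(cache=True)
def sweep(grid, n_steps, beta_comp, beta_col, gamma, delta, eta, r,
          neighborhood, lock_resolution, mixed_mortality, shield, rng):
    """Advance the lattice ``n_steps`` time steps (one step = H*W attempts)."""
    h, w = grid.shape
    n = h * w
    for _ in range(n_steps):
        for _ in range(n):
            idx = rng.integers(0, n)
            attempt_update(grid, idx // w, idx % w, beta_comp, beta_col,
                           gamma, delta, eta, r, neighborhood,
                           lock_resolution, mixed_mortality, shield, rng)


@njit(cache=True)
def state_counts(grid):
    """Counts of (vacant, competitor, colonizer, mixed) sites."""
    counts = np.zeros(4, dtype=np.int64)
    for v in grid.ravel():
        counts[v] += 1
    return counts


@njit(cache=True)
def run_trajectory(grid, burn_in, sample_steps, beta_comp, beta_col, gamma,
                   delta, eta, r, neighborhood, lock_resolution,
                   mixed_mortality, shield, rng):
    """Burn in, then record per-step species counts over the sampling window.

    Returns (n_comp, n_col, n_mixed) arrays of length ``sample_steps``,
    sampled after each completed time step.
    """
    sweep(grid, burn_in, beta_comp, beta_col, gamma, delta, eta, r,
          neighborhood, lock_resolution, mixed_mortality, shield, rng)
    n_comp = np.empty(sample_steps, dtype=np.int64)
    n_col = np.empty(sample_steps, dtype=np.int64)
    n_mix = np.empty(sample_steps, dtype=np.int64)
    for t in range(sample_steps):
        sweep(grid, 1, beta_comp, beta_col, gamma, delta, eta, r,
              neighborhood, lock_resolution, mixed_mortality, shield, rng)
        c = state_counts(grid)
        n_comp[t] = c[1]
        n_col[t] = c[2]
        n_mix[t] = c[3]
    return n_comp, n_col, n_mix
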