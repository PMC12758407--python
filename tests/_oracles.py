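"""Independent brute-force reimplementations used as oracles.

Everything here works by direct loops over individual records (or a dense
grid scan for the Euler-Lotka root) and deliberately shares no code with the
package's vectorized implementations.
"""

import math

import numpy as np


def tally_counts(cohort):
    """n_xj by direct per-day counting over raw records."""
    order = cohort.stage_order
    width = max(len(ind.stages) for ind in cohort.individuals)
    counts = {}
    for ind in cohort.individuals:
        for age, stage in enumerate(ind.stages):
            counts[(age, stage)] = counts.get((age, stage), 0) + 1
    mat = np.zeros((width, order.beta), dtype=int)
    for (age, stage), c in counts.items():
        mat[age, order.stages.index(stage)] = c
    return mat


def lx_brute(cohort):
    """Survivors at each age divided by n01."""
    width = max(len(ind.stages) for ind in cohort.individuals)
    out = np.zeros(width)
    for x in range(width):
        alive = sum(1 for ind in cohort.individuals if len(ind.stages) > x)
        out[x] = alive / cohort.n01
    return out


def mx_brute(cohort):
    """Eggs laid at age x divided by survivors at age x (0 when none)."""
    width = max(len(ind.stages) for ind in cohort.individuals)
    out = np.zeros(width)
    for x in range(width):
        alive = sum(1 for ind in cohort.individuals if len(ind.stages) > x)
        eggs = sum(ind.fecundity.get(x, 0) for ind in cohort.individuals)
        out[x] = eggs / alive if alive else 0.0
    return out


def R0_brute(cohort):
    """Total eggs laid by the cohort divided by n01 (conservation)."""
    total = sum(sum(ind.fecundity.values()) for ind in cohort.individuals)
    return total / cohort.n01


def sxj_brute(cohort):
    return tally_counts(cohort) / cohort.n01


def euler_lotka_residual(r, lxmx):
    return sum(v * math.exp(-r * (x + 1)) for x, v in enumerate(lxmx)) - 1.0


def r_gridscan(lxmx, coarse=1e-2, fine=1e-6):
    """Euler-Lotka root by sign-change grid scan refined by bisection.

    Coarse scan over [-1, 1] (extended outward if needed) locates the sign
    change; a fine grid at step 1e-6 narrows it; plain bisection on that
    final interval polishes to ~1e-13.
    """
    lo, hi = -1.0, 1.0
    while euler_lotka_residual(lo, lxmx) <= 0:
        lo *= 2
    while euler_lotka_residual(hi, lxmx) >= 0:
        hi *= 2
    # coarse grid
    g = lo
    while g < hi:
        if euler_lotka_residual(g + coarse, lxmx) < 0:
            lo, hi = g, g + coarse
            break
        g += coarse
    # fine grid, step 1e-6
    g = lo
    while g < hi:
        if euler_lotka_residual(g + fine, lxmx) < 0:
            lo, hi = g, g + fine
            break
        g += fine
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if euler_lotka_residual(mid, lxmx) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def mean_lifespan(cohort):
    return sum(len(ind.stages) for ind in cohort.individuals) / cohort.n01
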