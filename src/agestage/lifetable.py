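r"""Age-stage, two-sex life table computations.

Quantities, indexed by age ``x`` (days since entering the table) and stage
``j``:

* ``s_xj = n_xj / n01`` — probability a newborn is alive and in stage ``j``
  at age ``x``;
* ``l_x = Σ_j s_xj`` — age-specific survival;
* ``f_xj`` — mean eggs per individual in stage ``j`` at age ``x``;
* ``m_x = Σ_j s_xj f_xj / Σ_j s_xj`` — age-specific fecundity;
* ``R0 = Σ_x l_x m_x`` — net reproductive rate;
* ``r`` — intrinsic rate of increase, the root of the Euler-Lotka equation
  ``Σ_x e^{-r(x+1)} l_x m_x = 1`` (age-0 census, one-day interval, the
  ``x+1`` exponent convention);
* ``λ = e^r`` — finite rate of increase; ``T = ln(R0)/r`` — mean generation
  time;
* ``e_xj`` — life expectancy (expected remaining days, counting the current
  day) of an individual at age ``x``, stage ``j``;
* ``v_xj`` — reproductive value, the discounted expected future reproduction
  of an individual at age ``x``, stage ``j``; ``v_{0,1} = λ``.

Both sexes (and individuals dying before sex determination) contribute to
survival; only adult females carry fecundity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cohort import CohortTable, CohortError, StageOrder

__all__ = [
    "AgeStageMatrix",
    "AgeSchedules",
    "PopulationParameters",
    "LifeTableResult",
    "build_age_stage_matrix",
    "compute_sxj",
    "compute_lx",
    "compute_mx",
    "age_schedules",
    "compute_R0",
    "solve_r",
    "compute_T",
    "compute_lambda",
    "population_parameters",
    "compute_exj",
    "compute_vxj",
    "life_table",
]


@dataclass
class AgeStageMatrix:
    """Counts ``n_xj``, survival ``s_xj`` and fecundity ``f_xj`` on an
    (age, stage) grid of shape (max_age+1, beta)."""

    stage_order: StageOrder
    n01: int
    counts: np.ndarray
    fecundity: np.ndarray
    survival: Optional[np.ndarray] = None

    @property
    def max_age(self) -> int:
        return self.counts.shape[0] - 1


@dataclass
class AgeSchedules:
    """Age-indexed vectors l_x, m_x and their product l_x·m_x."""

    lx: np.ndarray
    mx: np.ndarray
    lxmx: np.ndarray


@dataclass
class PopulationParameters:
    """Demographic parameters of one cohort (per-day time unit).

    ``T`` is NaN when r = 0 (ln(R0)/r is 0/0 there).
    """

    r: float
    lam: float
    R0: float
    T: float


def build_age_stage_matrix(cohort: CohortTable) -> AgeStageMatrix:
    """Tabulate daily records into n_xj counts and f_xj fecundities.

    ``f_xj`` is total eggs laid at age x by stage-j individuals divided by
    ``n_xj`` (0 where the cell is empty); only the adult-female column can be
    nonzero.
    """
    cohort.validate()
    H, eggs, _ = cohort.to_arrays()
    beta = cohort.stage_order.beta
    width = H.shape[1]
    counts = np.zeros((width, beta), dtype=np.int64)
    egg_tot = np.zeros((width, beta), dtype=np.float64)
    for j in range(beta):
        mask = H == j
        counts[:, j] = mask.sum(axis=0)
        egg_tot[:, j] = np.where(mask, eggs, 0.0).sum(axis=0)
    fec = np.divide(egg_tot, counts, out=np.zeros_like(egg_tot), where=counts > 0)
    return AgeStageMatrix(cohort.stage_order, cohort.n01, counts, fec)


def compute_sxj(matrix: AgeStageMatrix, n01: Optional[int] = None) -> AgeStageMatrix:
    """Fill the survival slab: s_xj = n_xj / n01."""
    n01 = matrix.n01 if n01 is None else n01
    if n01 <= 0:
        raise CohortError("n01 must be positive")
    matrix.survival = matrix.counts / float(n01)
    return matrix


def _require_survival(matrix: AgeStageMatrix) -> np.ndarray:
    if matrix.survival is None:
        compute_sxj(matrix)
    return matrix.survival  # type: ignore[return-value]


def compute_lx(matrix: AgeStageMatrix) -> np.ndarray:
    """Age-specific survival l_x = Σ_j s_xj."""
    return _require_survival(matrix).sum(axis=1)


def compute_mx(matrix: AgeStageMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Age-specific fecundity m_x and the reproductive schedule l_x·m_x.

    m_x = Σ_j s_xj f_xj / Σ_j s_xj, defined as 0 at ages with no survivors
    (such ages contribute nothing to R0 or the Euler-Lotka sum).
    """
    s = _require_survival(matrix)
    num = (s * matrix.fecundity).sum(axis=1)
    lx = s.sum(axis=1)
    mx = np.divide(num, lx, out=np.zeros_like(num), where=lx > 0)
    return mx, lx * mx


def age_schedules(matrix: AgeStageMatrix) -> AgeSchedules:
    lx = compute_lx(matrix)
    mx, lxmx = compute_mx(matrix)
    return AgeSchedules(lx=lx, mx=mx, lxmx=lxmx)


def compute_R0(schedules: AgeSchedules) -> float:
    """Net reproductive rate R0 = Σ_x l_x m_x (offspring per newborn)."""
    return float(schedules.lxmx.sum())


def _solve_r_from_lxmx(lxmx: np.ndarray, tol: float = 1e-12,
                       max_iter: int = 400) -> float:
    idx = np.nonzero(lxmx)[0]
    if idx.size == 0:
        raise CohortError("no reproduction; r undefined")
    ages1 = (idx + 1).astype(np.float64)
    w = lxmx[idx]

    def residual(r: float) -> float:
        with np.errstate(over="ignore"):
            return float(np.exp(-r * ages1) @ w) - 1.0

    f0 = residual(0.0)
    if abs(f0) <= tol:
        return 0.0
    # residual is strictly decreasing in r; bracket by doubling outward
    lo, hi = -1.0, 1.0
    while residual(lo) <= 0.0:
        lo *= 2.0
        if not math.isfinite(lo) or lo < -1e6:
            raise CohortError("failed to bracket the Euler-Lotka root")
    while residual(hi) >= 0.0:
        hi *= 2.0
        if hi > 1e6:
            raise CohortError("failed to bracket the Euler-Lotka root")
    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = residual(mid)
        if abs(fm) <= tol:
            return mid
        if fm > 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 4.0 * np.finfo(float).eps * max(1.0, abs(mid)):
            break
    return mid


def solve_r(schedules: AgeSchedules, tol: float = 1e-12) -> float:
    """Intrinsic rate of increase: the unique real root of
    Σ_x e^{-r(x+1)} l_x m_x = 1, found by bracketed bisection
    (derivative-free, robust to spiky reproductive schedules).

    Raises if the schedule carries no reproduction (R0 = 0).
    """
    return _solve_r_from_lxmx(np.asarray(schedules.lxmx, dtype=float), tol=tol)


def compute_T(R0: float, r: float) -> float:
    """Mean generation time T = ln(R0)/r; NaN when r = 0 (0/0)."""
    if R0 <= 0:
        raise CohortError("T undefined for R0 <= 0")
    if r == 0.0:
        return math.nan
    return math.log(R0) / r


def compute_lambda(r: float) -> float:
    """Finite rate of increase λ = e^r (per-day population multiplier)."""
    return math.exp(r)


def population_parameters(schedules: AgeSchedules) -> PopulationParameters:
    R0 = compute_R0(schedules)
    r = solve_r(schedules)
    return PopulationParameters(r=r, lam=compute_lambda(r), R0=R0,
                                T=compute_T(R0, r))


def compute_exj(cohort: CohortTable) -> np.ndarray:
    """Age-stage life expectancy e_xj.

    Forward accumulation of the empirical conditional survival of the
    individuals observed in cell (x, j): e_xj is their mean remaining days
    alive, counting the current day (an individual on its last day has
    expectancy 1).  Cells never occupied are NaN.
    """
    cohort.validate()
    H, _, death = cohort.to_arrays()
    width = H.shape[1]
    beta = cohort.stage_order.beta
    e = np.full((width, beta), np.nan)
    for x in range(width):
        col = H[:, x]
        remaining = death - x + 1
        for j in np.unique(col[col >= 0]):
            members = col == j
            e[x, j] = remaining[members].mean()
    return e


def compute_vxj(cohort: CohortTable, r: float) -> np.ndarray:
    """Age-stage reproductive value v_xj.

    v_xj = e^{r(x+1)} Σ_{i>=x} e^{-r(i+1)} Σ_y P(alive in (i,y) | in (x,j)) f_iy,
    with the conditional occupation probabilities taken empirically from the
    individuals observed in cell (x, j).  Conditioning on a newborn recovers
    the Euler-Lotka sum, so v_{0,1} = e^r = λ.  Cells never occupied are NaN.
    """
    cohort.validate()
    H, _, _ = cohort.to_arrays()
    matrix = compute_sxj(build_age_stage_matrix(cohort))
    width = H.shape[1]
    beta = cohort.stage_order.beta
    ages = np.arange(width)
    disc = np.exp(-r * (ages + 1.0))
    # per-individual discounted future group-fecundity: g[m, i] = e^{-r(i+1)} f_{i, stage(m,i)}
    fx = matrix.fecundity
    g = np.where(H >= 0, fx[ages[None, :], np.clip(H, 0, beta - 1)], 0.0) * disc
    G = np.cumsum(g[:, ::-1], axis=1)[:, ::-1]  # suffix sums: Σ_{i>=x}
    v = np.full((width, beta), np.nan)
    grow = np.exp(r * (ages + 1.0))
    for x in range(width):
        col = H[:, x]
        for j in np.unique(col[col >= 0]):
            members = col == j
            v[x, j] = grow[x] * G[members, x].mean()
    return v


@dataclass
class LifeTableResult:
    """Bundle of everything the analysis derives from one cohort."""

    matrix: AgeStageMatrix
    schedules: AgeSchedules
    params: PopulationParameters
    exj: np.ndarray
    vxj: np.ndarray


def life_table(cohort: CohortTable) -> LifeTableResult:
    """Full pipeline: tabulate, derive schedules, solve the demographic
    parameters, and compute the age-stage expectancy and reproductive value."""
    matrix = compute_sxj(build_age_stage_matrix(cohort))
    sched = age_schedules(matrix)
    params = population_parameters(sched)
    return LifeTableResult(matrix=matrix, schedules=sched, params=params,
                           exj=compute_exj(cohort),
                           vxj=compute_vxj(cohort, params.r))


# ---------------------------------------------------------------------------
# fast array path (shared with the bootstrap)

def _schedules_from_arrays(death: np.ndarray, eggs_by_age: np.ndarray,
                           n01: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    """(lx, lxmx) from death days and total eggs per age for one (re)sample."""
    alive_until = np.bincount(death, minlength=width)
    survivors = alive_until[::-1].cumsum()[::-1]
    lx = survivors / n01
    lxmx = eggs_by_age / n01
    return lx, lxmx


def _params_from_arrays(death: np.ndarray, eggs_by_age: np.ndarray,
                        n01: int, width: int) -> Optional[tuple[float, float, float, float]]:
    """(r, λ, R0, T) for one resample; None when R0 = 0 (draw invalid)."""
    _, lxmx = _schedules_from_arrays(death, eggs_by_age, n01, width)
    R0 = float(lxmx.sum())
    if R0 <= 0.0:
        return None
    r = _solve_r_from_lxmx(lxmx)
    T = math.nan if r == 0.0 else math.log(R0) / r
    return r, math.exp(r), R0, T
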