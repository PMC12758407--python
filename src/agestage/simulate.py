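"""Synthetic rearing-cohort simulator.

Generates per-individual life histories with the statistical structure the
life table analysis assumes: independent per-stage durations (fixed or
shifted negative-binomial), daily geometric survival per stage, sex assigned
at pupation, and a unimodal daily fecundity schedule for adult females.  For
the deterministic-duration subfamily the exact expected schedules (and hence
the true r, λ, R0, T) are available in closed form, which is what makes the
simulator usable as a parameter-recovery oracle.

The bundled presets loosely mimic the phenotypes of a noctuid moth reared on
two artificial diets (a corn-flour-based formulation and a soybean-based
control): larval span ≈ 19.5 vs ≈ 22 days, pupal span ≈ 10.5 vs ≈ 11 days,
survival to pupation ≈ 0.84 vs ≈ 0.81, and lifetime fecundity in the low
thousands of eggs per female.  They are plausible fixtures, not fits to any
particular data set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .cohort import CohortTable, CohortError, IndividualRecord, StageOrder
from .lifetable import _solve_r_from_lxmx

__all__ = [
    "Duration",
    "SimulationConfig",
    "ExpectedSchedules",
    "fecundity_kernel",
    "simulate_cohort",
    "expected_schedules",
    "diet15_config",
    "control_config",
]


@dataclass(frozen=True)
class Duration:
    """Distribution of one stage's duration, in whole days (>= 1).

    Either a fixed value or 1 + NegativeBinomial(size, p) — the shift keeps
    every stage at least one day long.
    """

    kind: str  # "fixed" | "nbinom"
    value: int = 0
    size: float = 0.0
    p: float = 0.0

    @classmethod
    def fixed(cls, days: int) -> "Duration":
        if days < 1:
            raise CohortError("stage duration must be >= 1 day")
        return cls(kind="fixed", value=int(days))

    @classmethod
    def negative_binomial(cls, size: float, p: float) -> "Duration":
        if size <= 0 or not (0 < p <= 1):
            raise CohortError("negative-binomial duration needs size > 0, 0 < p <= 1")
        return cls(kind="nbinom", size=float(size), p=float(p))

    @property
    def is_fixed(self) -> bool:
        return self.kind == "fixed"

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            return self.value
        return 1 + int(rng.negative_binomial(self.size, self.p))

    def mean(self) -> float:
        if self.kind == "fixed":
            return float(self.value)
        return 1.0 + self.size * (1.0 - self.p) / self.p


@dataclass
class SimulationConfig:
    """Generating model for one rearing cohort.

    ``durations`` and ``survival`` (daily survival probability in (0, 1])
    are keyed by stage label.  ``female_fraction`` applies at pupation.
    An adult female lays nothing for ``preoviposition_days`` adult days, then
    follows a discretized-Gaussian daily schedule with mode
    ``fecundity_peak`` (0-based oviposition day) and spread
    ``fecundity_spread`` (days), normalized so a female surviving her whole
    adult span lays ``total_fecundity`` eggs exactly (largest-remainder
    rounding to whole eggs per day).
    """

    stage_order: StageOrder = field(default_factory=StageOrder.default)
    n: int = 100
    durations: Mapping[str, Duration] = field(default_factory=dict)
    survival: Mapping[str, float] = field(default_factory=dict)
    female_fraction: float = 0.5
    total_fecundity: float = 2658.0
    preoviposition_days: int = 2
    fecundity_peak: int = 4
    fecundity_spread: float = 4.0
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n < 1:
            raise CohortError("cohort size n must be >= 1")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise CohortError("female_fraction must lie in [0, 1]")
        if self.total_fecundity < 0:
            raise CohortError("total_fecundity must be >= 0")
        if self.preoviposition_days < 0:
            raise CohortError("preoviposition_days must be >= 0")
        if self.fecundity_spread <= 0:
            raise CohortError("fecundity_spread must be > 0")
        for s in self.stage_order.stages:
            if s not in self.durations:
                raise CohortError(f"no duration configured for stage {s!r}")
            if s not in self.survival:
                raise CohortError(f"no daily survival configured for stage {s!r}")
            if not (0.0 < self.survival[s] <= 1.0):
                raise CohortError(f"daily survival for {s!r} must lie in (0, 1]")
        return self


@dataclass
class ExpectedSchedules:
    """Closed-form l_x / m_x and true demographic parameters for a
    deterministic-duration configuration (``true_r``/``true_T``/
    ``true_lambda`` are NaN when R0 = 0)."""

    lx: np.ndarray
    mx: np.ndarray
    lxmx: np.ndarray
    true_r: float
    true_R0: float
    true_T: float
    true_lambda: float


def fecundity_kernel(total: float, n_days: int, peak: int, spread: float) -> np.ndarray:
    """Integer eggs per oviposition day: discretized Gaussian bump scaled to
    ``total`` with largest-remainder rounding (so the sum is round(total))."""
    if n_days <= 0 or total <= 0:
        return np.zeros(max(n_days, 0), dtype=np.int64)
    d = np.arange(n_days, dtype=float)
    w = np.exp(-0.5 * ((d - peak) / spread) ** 2)
    raw = total * w / w.sum()
    base = np.floor(raw).astype(np.int64)
    short = int(round(total)) - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def _stage_paths(cfg: SimulationConfig,
                 durations: Mapping[str, int]) -> tuple[list[int], list[int], list[int]]:
    """(shared pre-adult path, female path, male path) as stage-code-per-day
    lists, given realized whole-day durations."""
    order = cfg.stage_order
    shared: list[int] = []
    for k, s in enumerate(order.stages[:-2]):
        shared.extend([k] * durations[s])
    female = shared + [order.beta - 2] * durations[order.adult_female]
    male = shared + [order.beta - 1] * durations[order.adult_male]
    return shared, female, male


def _female_egg_days(cfg: SimulationConfig, adult_days: int) -> np.ndarray:
    eggs = np.zeros(adult_days, dtype=np.int64)
    ovi = adult_days - cfg.preoviposition_days
    if ovi > 0:
        eggs[cfg.preoviposition_days:] = fecundity_kernel(
            cfg.total_fecundity, ovi, cfg.fecundity_peak, cfg.fecundity_spread)
    return eggs


def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Draw one cohort; a fixed config (including its seed) reproduces the
    cohort exactly."""
    cfg = config.validate()
    order = cfg.stage_order
    rng = np.random.default_rng(cfg.seed)
    surv = np.array([cfg.survival[s] for s in order.stages])
    sexing_code = order.sexing_index
    individuals: list[IndividualRecord] = []
    for i in range(cfg.n):
        is_female = rng.random() < cfg.female_fraction
        durs = {s: cfg.durations[s].sample(rng) for s in order.stages}
        shared, fpath, mpath = _stage_paths(cfg, durs)
        path = np.array(fpath if is_female else mpath, dtype=np.int64)
        D = len(path)
        # survive the transition after each day d with the stage-d daily rate
        u = rng.random(D - 1) if D > 1 else np.empty(0)
        fails = np.nonzero(u >= surv[path[:-1]])[0]
        last = int(fails[0]) if fails.size else D - 1
        reached_sexing = bool((path[: last + 1] >= sexing_code).any())
        sex = ("F" if is_female else "M") if reached_sexing else "U"
        fecundity: dict[int, int] = {}
        if is_female and sex == "F":
            adult_start = len(shared)
            if last >= adult_start:
                eggs = _female_egg_days(cfg, durs[order.adult_female])
                for k in range(min(last - adult_start, len(eggs) - 1) + 1):
                    if eggs[k] > 0:
                        fecundity[adult_start + k] = int(eggs[k])
        stages = tuple(order.stages[k] for k in path[: last + 1])
        individuals.append(IndividualRecord(
            individual_id=f"ind{i:05d}", sex=sex, stages=stages, fecundity=fecundity))
    return CohortTable(individuals=individuals, stage_order=order).validate()


def expected_schedules(config: SimulationConfig) -> ExpectedSchedules:
    """Exact l_x / m_x implied by a deterministic-duration configuration.

    l_x is the sex-weighted product of daily survival along the two
    deterministic stage paths; the reproductive schedule is the female path's
    survival times the egg kernel.  ``true_r`` is then solved on these
    schedules with the same Euler-Lotka root-finder used for data.
    """
    cfg = config.validate()
    if not all(cfg.durations[s].is_fixed for s in cfg.stage_order.stages):
        raise CohortError("closed form requires deterministic durations")
    order = cfg.stage_order
    durs = {s: cfg.durations[s].value for s in order.stages}
    shared, fpath, mpath = _stage_paths(cfg, durs)
    surv = np.array([cfg.survival[s] for s in order.stages])

    def survival_curve(path: list[int], width: int) -> np.ndarray:
        # S[x] = P(alive on day x) = product of the first x daily rates
        p = surv[np.array(path, dtype=np.int64)]
        S = np.zeros(width)
        S[: len(path)] = np.concatenate(([1.0], np.cumprod(p[:-1])))
        return S

    width = max(len(fpath), len(mpath))
    Sf = survival_curve(fpath, width)
    Sm = survival_curve(mpath, width)
    ff = cfg.female_fraction
    lx = ff * Sf + (1.0 - ff) * Sm
    eggs_age = np.zeros(width)
    adult_start = len(shared)
    kernel = _female_egg_days(cfg, durs[order.adult_female])
    eggs_age[adult_start: adult_start + len(kernel)] = kernel
    lxmx = ff * Sf * eggs_age
    mx = np.divide(lxmx, lx, out=np.zeros_like(lxmx), where=lx > 0)
    R0 = float(lxmx.sum())
    if R0 > 0:
        r = _solve_r_from_lxmx(lxmx)
        lam = math.exp(r)
        T = math.nan if r == 0.0 else math.log(R0) / r
    else:
        r = lam = T = math.nan
    return ExpectedSchedules(lx=lx, mx=mx, lxmx=lxmx, true_r=r, true_R0=R0,
                             true_T=T, true_lambda=lam)


def _base_config(**overrides) -> SimulationConfig:
    order = StageOrder.default()
    cfg = SimulationConfig(stage_order=order, **overrides)
    return cfg


def diet15_config(n: int = 100, seed: int = 0) -> SimulationConfig:
    """Preset mimicking the corn-flour diet phenotype: larval span ≈ 19.5 d,
    pupa ≈ 10.5 d, survival ≈ 0.84 to pupation, ≈ 2,658 eggs per female with
    the fecundity peak around age 36."""
    durations = {
        "L1": Duration.fixed(3), "L2": Duration.fixed(3), "L3": Duration.fixed(3),
        "L4": Duration.fixed(3), "L5": Duration.fixed(3), "L6": Duration.fixed(5),
        "pupa": Duration.fixed(10),
        "adult_female": Duration.fixed(18), "adult_male": Duration.fixed(14),
    }
    survival = {
        "L1": 0.9913, "L2": 0.9913, "L3": 0.9913, "L4": 0.9913, "L5": 0.9913,
        "L6": 0.9913, "pupa": 0.998, "adult_female": 0.985, "adult_male": 0.985,
    }
    return _base_config(n=n, seed=seed, durations=durations, survival=survival,
                        female_fraction=0.5, total_fecundity=2658.0,
                        preoviposition_days=2, fecundity_peak=4,
                        fecundity_spread=4.0)


def control_config(n: int = 100, seed: int = 0) -> SimulationConfig:
    """Preset mimicking the soybean-based control diet: slower development
    (larval span ≈ 22 d, pupa ≈ 11 d), slightly lower survival, slightly
    higher lifetime fecundity — hence a higher net reproductive rate but a
    lower intrinsic rate of increase than the corn-flour preset."""
    durations = {
        "L1": Duration.fixed(4), "L2": Duration.fixed(3), "L3": Duration.fixed(3),
        "L4": Duration.fixed(4), "L5": Duration.fixed(4), "L6": Duration.fixed(4),
        "pupa": Duration.fixed(11),
        "adult_female": Duration.fixed(17), "adult_male": Duration.fixed(16),
    }
    survival = {
        "L1": 0.9905, "L2": 0.9905, "L3": 0.9905, "L4": 0.9905, "L5": 0.9905,
        "L6": 0.9905, "pupa": 0.997, "adult_female": 0.985, "adult_male": 0.985,
    }
    return _base_config(n=n, seed=seed, durations=durations, survival=survival,
                        female_fraction=0.5, total_fecundity=2900.0,
                        preoviposition_days=3, fecundity_peak=5,
                        fecundity_spread=4.5)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed (same biology)."""
    return replace(config, seed=seed)
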