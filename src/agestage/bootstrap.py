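"""Bootstrap inference for demographic parameters.

The resampling unit is the individual (a whole life history): each iteration
draws n01 individuals with replacement, rebuilds the life table, and
recomputes r, λ, R0 and T.  Draws in which the resample carries no
reproduction (R0 = 0 — no reproducing female drawn) are flagged invalid and
excluded from moments rather than treated as r = -∞; the number of valid
draws is reported.

The paired bootstrap test resamples two cohorts independently and examines
the distribution of per-iteration parameter differences; its two-sided
p-value is the sign-count form 2·min(#{d<=0}, #{d>=0})/B, clamped to 1.

Randomness is driven by one seed; per-iteration substreams are derived
deterministically (NumPy SeedSequence spawning), so results do not depend on
iteration order.  For the paired test each cohort's stream is additionally
keyed by a fingerprint of the cohort's content, which makes the p-value
exactly invariant under swapping the two cohorts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable, CohortError
from .lifetable import _params_from_arrays

__all__ = [
    "PARAMETERS",
    "BootstrapConfig",
    "BootstrapResult",
    "PairedTestResult",
    "bootstrap_parameters",
    "paired_bootstrap_test",
]

PARAMETERS = ("r", "lambda", "R0", "T")


@dataclass(frozen=True)
class BootstrapConfig:
    n_iter: int = 100_000
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise CohortError("bootstrap needs at least one iteration")
        if not (0.0 < self.ci_level < 1.0):
            raise CohortError("ci_level must lie in (0, 1)")


@dataclass
class BootstrapResult:
    parameter: str
    estimates: np.ndarray  # length B; NaN marks invalid/undefined draws
    mean: float
    se: float
    ci_low: float
    ci_high: float
    n_valid: int


@dataclass
class PairedTestResult:
    parameter: str
    diff_mean: float
    diff_se: float
    p_value: float
    n_iter: int
    n_valid: int


def _cohort_arrays(cohort: CohortTable):
    cohort.validate()
    _, eggs, death = cohort.to_arrays()
    return death, eggs, cohort.n01, eggs.shape[1]


def _draw(death, eggs, n01, width, rng):
    idx = rng.integers(0, n01, n01)
    return _params_from_arrays(death[idx], eggs[idx].sum(axis=0), n01, width)


def _draw_matrix(cohort: CohortTable, streams) -> np.ndarray:
    """B x 4 matrix of (r, λ, R0, T) over resamples; NaN rows are invalid."""
    death, eggs, n01, width = _cohort_arrays(cohort)
    out = np.full((len(streams), len(PARAMETERS)), np.nan)
    for b, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        params = _draw(death, eggs, n01, width, rng)
        if params is not None:
            out[b] = params
    return out


def _summary(name: str, col: np.ndarray, ci_level: float) -> BootstrapResult:
    valid = col[~np.isnan(col)]
    n_valid = valid.size
    if n_valid == 0:
        return BootstrapResult(name, col, np.nan, np.nan, np.nan, np.nan, 0)
    mean = float(valid.mean())
    se = float(valid.std(ddof=1)) if n_valid > 1 else 0.0
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(valid, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapResult(name, col, mean, se, float(lo), float(hi), n_valid)


def bootstrap_parameters(cohort: CohortTable,
                         config: BootstrapConfig) -> dict[str, BootstrapResult]:
    """Bootstrap means, standard errors and percentile CIs of r, λ, R0, T."""
    streams = np.random.SeedSequence(config.seed).spawn(config.n_iter)
    draws = _draw_matrix(cohort, streams)
    if np.isnan(draws[:, 0]).all():
        raise CohortError("cohort cannot support bootstrap: every resample had R0 = 0")
    return {name: _summary(name, draws[:, k], config.ci_level)
            for k, name in enumerate(PARAMETERS)}


def _fingerprint(cohort: CohortTable) -> int:
    _, eggs, death = cohort.to_arrays()
    h = zlib.crc32(death.tobytes())
    h = zlib.crc32(eggs.tobytes(), h)
    return h


def paired_bootstrap_test(cohort_a: CohortTable, cohort_b: CohortTable,
                          config: BootstrapConfig) -> dict[str, PairedTestResult]:
    """Two-sided paired bootstrap comparison of each demographic parameter.

    Iterations where either side's resample is invalid (R0 = 0) are dropped;
    the p-value denominator is the number of valid differences.
    """
    streams_a = np.random.SeedSequence([config.seed, _fingerprint(cohort_a)]).spawn(config.n_iter)
    streams_b = np.random.SeedSequence([config.seed, _fingerprint(cohort_b)]).spawn(config.n_iter)
    draws_a = _draw_matrix(cohort_a, streams_a)
    draws_b = _draw_matrix(cohort_b, streams_b)
    if np.isnan(draws_a[:, 0]).all():
        raise CohortError("first cohort cannot support bootstrap: every resample had R0 = 0")
    if np.isnan(draws_b[:, 0]).all():
        raise CohortError("second cohort cannot support bootstrap: every resample had R0 = 0")
    out: dict[str, PairedTestResult] = {}
    for k, name in enumerate(PARAMETERS):
        d = draws_a[:, k] - draws_b[:, k]
        d = d[~np.isnan(d)]
        n_valid = d.size
        if n_valid == 0:
            out[name] = PairedTestResult(name, np.nan, np.nan, np.nan,
                                         config.n_iter, 0)
            continue
        p = 2.0 * min(int((d <= 0).sum()), int((d >= 0).sum())) / n_valid
        out[name] = PairedTestResult(
            parameter=name,
            diff_mean=float(d.mean()),
            diff_se=float(d.std(ddof=1)) if n_valid > 1 else 0.0,
            p_value=min(p, 1.0),
            n_iter=config.n_iter,
            n_valid=n_valid,
        )
    return out
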