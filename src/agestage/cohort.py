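"""Cohort data model: individual life histories tracked by age and developmental stage.

The unit of observation is one individual followed daily from entry into the
life table (age 0, first stage) until death.  Sex is latent until pupation:
individuals dying earlier carry sex ``"U"`` and still contribute fully to
survival — the defining feature of the two-sex bookkeeping, which avoids the
female-only survivorship bias of classical female age-specific life tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["StageOrder", "IndividualRecord", "CohortTable", "CohortError"]

FEMALE = "F"
MALE = "M"
UNDETERMINED = "U"
_SEXES = (FEMALE, MALE, UNDETERMINED)


class CohortError(ValueError):
    """Raised when a cohort or individual record violates its invariants."""


@dataclass(frozen=True)
class StageOrder:
    """Ordered developmental stages; the last two are the sexed adult stages.

    The default models a noctuid moth reared from first instar: six larval
    instars, pupa, then adult female / adult male (beta = 9 stages).  The egg
    stage is excluded from the table (enrolment at L1) but eggs are counted
    as offspring.
    """

    stages: tuple[str, ...]
    sexing_stage: str | None = None

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise CohortError("stage order needs at least the two adult stages")
        if len(set(self.stages)) != len(self.stages):
            raise CohortError("stage labels must be unique")
        if self.sexing_stage is not None and self.sexing_stage not in self.stages:
            raise CohortError(f"sexing stage {self.sexing_stage!r} not in stage order")

    @classmethod
    def default(cls) -> "StageOrder":
        return cls(("L1", "L2", "L3", "L4", "L5", "L6", "pupa",
                    "adult_female", "adult_male"), sexing_stage="pupa")

    @property
    def beta(self) -> int:
        """Number of stages (the β of the age-stage formalism)."""
        return len(self.stages)

    @property
    def adult_female(self) -> str:
        return self.stages[-2]

    @property
    def adult_male(self) -> str:
        return self.stages[-1]

    @property
    def sexing_index(self) -> int:
        """Index of the stage at which sex becomes observable (pupation in
        the default order; the first adult stage when unspecified)."""
        if self.sexing_stage is not None:
            return self.stages.index(self.sexing_stage)
        return self.beta - 2

    def index(self, label: str) -> int:
        try:
            return self.stages.index(label)
        except ValueError:
            raise CohortError(f"unknown stage label {label!r}") from None


@dataclass(frozen=True)
class IndividualRecord:
    """One individual's daily life history.

    ``stages[x]`` is the stage occupied at age ``x`` (days); the sequence
    covers every day from age 0 to the last day alive, with the recorded
    stage on a molt day taken as authoritative.  ``fecundity`` maps age to
    eggs laid that day (females only, adult-female stage only).
    """

    individual_id: str
    sex: str
    stages: tuple[str, ...]
    fecundity: Mapping[int, int] = field(default_factory=dict)

    @property
    def last_age(self) -> int:
        return len(self.stages) - 1

    @property
    def lifespan(self) -> int:
        """Days alive, counting the day of entry."""
        return len(self.stages)

    @property
    def total_eggs(self) -> int:
        return sum(self.fecundity.values())

    def validate(self, order: StageOrder) -> None:
        ident = self.individual_id
        if self.sex not in _SEXES:
            raise CohortError(f"individual {ident!r}: sex must be one of {_SEXES}")
        if not self.stages:
            raise CohortError(f"individual {ident!r}: empty history")
        idx = [order.index(s) for s in self.stages]
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise CohortError(f"individual {ident!r}: stage regression in history")
        if self.sex == UNDETERMINED and max(idx) >= order.sexing_index:
            raise CohortError(
                f"individual {ident!r}: sex undetermined but reached the sexing stage")
        af, am = order.adult_female, order.adult_male
        if self.sex != FEMALE and af in self.stages:
            raise CohortError(f"individual {ident!r}: non-female in adult-female stage")
        if self.sex != MALE and am in self.stages:
            raise CohortError(f"individual {ident!r}: non-male in adult-male stage")
        for age, eggs in self.fecundity.items():
            if eggs < 0 or int(eggs) != eggs:
                raise CohortError(f"individual {ident!r}: negative/non-integer eggs at age {age}")
            if eggs == 0:
                continue
            if self.sex != FEMALE:
                raise CohortError(f"individual {ident!r}: eggs recorded for a non-female")
            if age > self.last_age or self.stages[age] != af:
                raise CohortError(
                    f"individual {ident!r}: eggs at age {age} outside the adult-female stage")


@dataclass
class CohortTable:
    """All individual life histories for one treatment; the unit of resampling.

    ``n01`` (newborns entering the table at age 0, stage 1) equals the number
    of individuals; every history must start at the first stage on day 0.
    """

    individuals: list[IndividualRecord]
    stage_order: StageOrder = field(default_factory=StageOrder.default)

    @property
    def n01(self) -> int:
        return len(self.individuals)

    @property
    def max_age(self) -> int:
        return max(ind.last_age for ind in self.individuals)

    @property
    def total_eggs(self) -> int:
        return sum(ind.total_eggs for ind in self.individuals)

    def validate(self) -> "CohortTable":
        if not self.individuals:
            raise CohortError("empty cohort")
        first = self.stage_order.stages[0]
        for ind in self.individuals:
            ind.validate(self.stage_order)
            if ind.stages[0] != first:
                raise CohortError(
                    f"individual {ind.individual_id!r}: history does not start at "
                    f"(age 0, {first!r})")
        ids = [ind.individual_id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise CohortError("duplicate individual ids")
        return self

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Compact numeric view: (stage codes, daily eggs, death day).

        Returns ``H`` of shape (n, max_age+1) with the stage index per day and
        -1 after death, ``eggs`` of the same shape, and ``death`` (last day
        alive) of shape (n,).  This is the fast path used by the life table
        builder and the bootstrap.
        """
        if not self.individuals:
            raise CohortError("empty cohort")
        n = self.n01
        width = self.max_age + 1
        H = np.full((n, width), -1, dtype=np.int16)
        eggs = np.zeros((n, width), dtype=np.float64)
        death = np.empty(n, dtype=np.int64)
        lookup = {s: k for k, s in enumerate(self.stage_order.stages)}
        for i, ind in enumerate(self.individuals):
            codes = [lookup[s] for s in ind.stages]
            H[i, : len(codes)] = codes
            death[i] = ind.last_age
            for age, e in ind.fecundity.items():
                eggs[i, age] = e
        return H, eggs, death
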