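"""Artificial-diet formulations and cost comparisons.

Eighteen diet formulations (the soybean-based control CK plus variants 1-17
that progressively substitute maize powder for soybean powder and vary the
yeast/wheat-bran ratio) with their per-batch costs in yuan.  Ingredient unit
prices are not part of the data, so costs are fixture values, not derived;
the additive set (vitamin C, niptibet, sorbic acid, cholesterol) is common
to every formulation.

Formulations were designed in three cost tiers of six diets each
(high / medium / low), encoded in :data:`COST_TIERS`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

__all__ = [
    "DietFormulation",
    "CostComparison",
    "ADDITIVES_G",
    "COST_TIERS",
    "load_formulations",
    "get_formulation",
    "compare_costs",
    "rank_by_cost",
]

ADDITIVES_G = {
    "vitamin_c": 4.0,
    "niptibet": 2.0,
    "sorbic_acid": 2.0,
    "cholesterol": 0.8,
}

COST_TIERS = {
    "high": ("CK", "3", "6", "9", "12", "15"),
    "medium": ("1", "4", "7", "10", "13", "16"),
    "low": ("2", "5", "8", "11", "14", "17"),
}

# name, maize g, soybean g, yeast g, wheat bran g, cost (yuan per batch)
_TABLE: tuple[tuple[str, float, float, float, float, float], ...] = (
    ("CK", 0, 100, 40, 60, 42.32),
    ("1", 0, 100, 20, 80, 36.68),
    ("2", 0, 100, 0, 100, 31.04),
    ("3", 20, 80, 40, 60, 41.82),
    ("4", 20, 80, 20, 80, 36.18),
    ("5", 20, 80, 0, 100, 30.54),
    ("6", 40, 60, 40, 60, 41.32),
    ("7", 40, 60, 20, 80, 35.68),
    ("8", 40, 60, 0, 100, 30.04),
    ("9", 60, 40, 40, 60, 39.80),
    ("10", 60, 40, 20, 80, 35.15),
    ("11", 60, 40, 0, 100, 30.04),
    ("12", 80, 20, 40, 60, 40.32),
    ("13", 80, 20, 20, 80, 34.68),
    ("14", 80, 20, 0, 100, 29.04),
    ("15", 100, 0, 40, 60, 39.82),
    ("16", 100, 0, 20, 80, 34.18),
    ("17", 100, 0, 0, 100, 28.54),
)

_CHECKSUM = "c41d739ebe91604d086a806554d77c72d955aedd020900d1fe07a53a701bbd03"


@dataclass(frozen=True)
class DietFormulation:
    name: str
    maize_g: float
    soybean_g: float
    yeast_g: float
    wheat_bran_g: float
    cost: float

    def validate(self) -> "DietFormulation":
        if abs(self.maize_g + self.soybean_g - 100.0) > 1e-9:
            raise ValueError(f"diet {self.name}: maize + soybean must total 100 g")
        if abs(self.yeast_g + self.wheat_bran_g - 100.0) > 1e-9:
            raise ValueError(f"diet {self.name}: yeast + wheat bran must total 100 g")
        if self.cost <= 0:
            raise ValueError(f"diet {self.name}: cost must be positive")
        return self


@dataclass(frozen=True)
class CostComparison:
    reference: str
    candidate: str
    absolute_diff: float          # yuan saved by the candidate (negative if dearer)
    relative_reduction_pct: float


def _canonical() -> str:
    return "\n".join(
        f"{n},{m:g},{s:g},{y:g},{w:g},{c:.2f}" for n, m, s, y, w, c in _TABLE)


def load_formulations() -> list[DietFormulation]:
    """The 18 bundled formulations (CK and 1-17), checksum-verified."""
    digest = hashlib.sha256(_canonical().encode()).hexdigest()
    if digest != _CHECKSUM:
        raise ValueError("diet formulation fixture corrupted (checksum mismatch)")
    return [DietFormulation(*row).validate() for row in _TABLE]


def get_formulation(name: str) -> DietFormulation:
    for f in load_formulations():
        if f.name == name:
            return f
    raise KeyError(f"unknown diet formulation {name!r}")


def compare_costs(reference: DietFormulation, candidate: DietFormulation,
                  round_to: int = 1) -> CostComparison:
    """Cost saving of ``candidate`` relative to ``reference``.

    Absolute difference in yuan (rounded to 2 decimals) and relative
    reduction in percent of the reference cost (rounded to ``round_to``
    decimals).
    """
    if reference.cost == 0:
        raise ValueError("reference cost must be nonzero")
    diff = reference.cost - candidate.cost
    pct = 100.0 * diff / reference.cost
    return CostComparison(
        reference=reference.name,
        candidate=candidate.name,
        absolute_diff=round(diff, 2),
        relative_reduction_pct=round(pct, round_to),
    )


def cost_tier(name: str) -> str:
    for tier, members in COST_TIERS.items():
        if name in members:
            return tier
    raise KeyError(f"diet {name!r} is not in any cost tier")


def rank_by_cost(formulations: list[DietFormulation]) -> list[tuple[DietFormulation, str]]:
    """Stable ascending sort by cost, each formulation tagged with its
    design cost tier."""
    if not formulations:
        raise ValueError("no formulations to rank")
    ranked = sorted(formulations, key=lambda f: f.cost)
    return [(f, cost_tier(f.name)) for f in ranked]
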