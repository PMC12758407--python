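import numpy as np
import pytest

from agestage import (CohortTable, IndividualRecord, StageOrder, diet15_config,
                      simulate_cohort, with_seed)
from agestage.simulate import Duration, SimulationConfig


@pytest.fixture
def order():
    return StageOrder.default()


def make_individual(ident, sex, stages, fecundity=None):
    return IndividualRecord(individual_id=ident, sex=sex, stages=tuple(stages),
                            fecundity=fecundity or {})


@pytest.fixture
def tiny_order():
    """Minimal three-stage order: one juvenile stage plus the sexed adults."""
    return StageOrder(("J", "AF", "AM"))


@pytest.fixture
def identical_cohort(tiny_order):
    """Four identical reproducing females: zero resampling variance."""
    inds = [make_individual(f"i{k}", "F", ["J", "J", "AF", "AF"], {2: 10, 3: 6})
            for k in range(4)]
    return CohortTable(individuals=inds, stage_order=tiny_order).validate()


@pytest.fixture
def small_cohort(order):
    """Simulated 40-individual cohort, fixed seed."""
    return simulate_cohort(diet15_config(n=40, seed=11))


@pytest.fixture
def medium_cohort(order):
    return simulate_cohort(diet15_config(n=100, seed=7))


def toy_two_age_config():
    """One juvenile day then one adult day laying 2 eggs: lx=[1,1], mx=[0,2]."""
    so = StageOrder(("J", "AF", "AM"))
    return SimulationConfig(
        stage_order=so, n=50,
        durations={"J": Duration.fixed(1), "AF": Duration.fixed(1),
                   "AM": Duration.fixed(1)},
        survival={"J": 1.0, "AF": 1.0, "AM": 1.0},
        female_fraction=1.0, total_fecundity=2.0,
        preoviposition_days=0, fecundity_peak=0, fecundity_spread=1.0,
        seed=0)
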