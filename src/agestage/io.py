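"""File formats: cohort CSV, simulator config (YAML), result reports.

Cohort CSV is long format, one row per individual-day, UTF-8, comma
separated, with a required header::

    individual_id,sex,age_day,stage,eggs

``sex`` is F/M/U, ``age_day`` integers starting at 0 with no gaps, ``stage``
a label from the configured stage order, ``eggs`` a non-negative integer
(0 default).  Validation failures are reported with the offending file line
number (header = line 1).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, TextIO, Union

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, CohortError, IndividualRecord, StageOrder
from .lifetable import LifeTableResult
from .simulate import Duration, SimulationConfig

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort_csv",
    "write_cohort_csv",
    "cohort_to_csv_text",
    "read_simulation_config",
    "write_report",
    "write_life_table_outputs",
]

COHORT_COLUMNS = ["individual_id", "sex", "age_day", "stage", "eggs"]

PathLike = Union[str, Path]


def _err(line: int, msg: str) -> CohortError:
    return CohortError(f"line {line}: {msg}")


def read_cohort_csv(path: PathLike, stage_order: Optional[StageOrder] = None) -> CohortTable:
    """Load and validate a cohort CSV into a :class:`CohortTable`."""
    order = stage_order or StageOrder.default()
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CohortError("empty cohort") from None
    for col in COHORT_COLUMNS[:-1]:
        if col not in df.columns:
            raise CohortError(f"missing column {col!r}")
    if "eggs" not in df.columns:
        df["eggs"] = "0"
    if len(df) == 0:
        raise CohortError("empty cohort")
    df["_line"] = np.arange(2, len(df) + 2)  # header is line 1

    stage_set = set(order.stages)
    individuals: list[IndividualRecord] = []
    seen: set[str] = set()
    for ident, rows in df.groupby("individual_id", sort=False):
        if ident in seen:  # groupby(sort=False) keeps one group per key anyway
            continue
        seen.add(ident)
        sexes = set(rows["sex"])
        if not sexes <= {"F", "M", "U"}:
            bad = rows[~rows["sex"].isin(["F", "M", "U"])].iloc[0]
            raise _err(int(bad["_line"]), f"individual {ident!r}: invalid sex {bad['sex']!r}")
        if len(sexes) > 1:
            raise _err(int(rows["_line"].iloc[0]),
                       f"individual {ident!r}: inconsistent sex codes {sorted(sexes)}")
        stages: list[str] = []
        fecundity: dict[int, int] = {}
        prev_age = -1
        prev_idx = -1
        for _, row in rows.iterrows():
            line = int(row["_line"])
            try:
                age = int(row["age_day"])
            except ValueError:
                raise _err(line, f"individual {ident!r}: non-integer age_day {row['age_day']!r}")
            if age != prev_age + 1:
                raise _err(line, f"individual {ident!r}: age_day jumps from "
                                 f"{prev_age} to {age} (days must be consecutive from 0)")
            stage = row["stage"]
            if stage not in stage_set:
                raise _err(line, f"individual {ident!r}: unknown stage {stage!r}")
            idx = order.index(stage)
            if idx < prev_idx:
                raise _err(line, f"individual {ident!r}: stage regression to {stage!r}")
            try:
                eggs = int(row["eggs"]) if row["eggs"] != "" else 0
            except ValueError:
                raise _err(line, f"individual {ident!r}: non-integer eggs {row['eggs']!r}")
            if eggs < 0:
                raise _err(line, f"individual {ident!r}: negative eggs")
            if eggs > 0:
                if row["sex"] != "F":
                    raise _err(line, f"individual {ident!r}: eggs recorded for sex "
                                     f"{row['sex']!r}")
                if stage != order.adult_female:
                    raise _err(line, f"individual {ident!r}: eggs outside the "
                                     f"adult-female stage")
                fecundity[age] = eggs
            stages.append(stage)
            prev_age, prev_idx = age, idx
        individuals.append(IndividualRecord(
            individual_id=str(ident), sex=rows["sex"].iloc[0],
            stages=tuple(stages), fecundity=fecundity))
    return CohortTable(individuals=individuals, stage_order=order).validate()


def cohort_to_csv_text(cohort: CohortTable) -> str:
    buf = _io.StringIO()
    buf.write(",".join(COHORT_COLUMNS) + "\n")
    for ind in cohort.individuals:
        for age, stage in enumerate(ind.stages):
            eggs = ind.fecundity.get(age, 0)
            buf.write(f"{ind.individual_id},{ind.sex},{age},{stage},{eggs}\n")
    return buf.getvalue()


def write_cohort_csv(cohort: CohortTable, path: PathLike) -> None:
    Path(path).write_text(cohort_to_csv_text(cohort), encoding="utf-8")


_DEFAULT_SURVIVAL = 1.0


def read_simulation_config(path: PathLike) -> SimulationConfig:
    """Parse a YAML simulator configuration.

    Layout::

        stages: [L1, ..., pupa, adult_female, adult_male]
        n: 100
        seed: 1
        female_fraction: 0.5
        total_fecundity: 2658
        preoviposition_days: 2
        fecundity_peak: 4
        fecundity_spread: 4.0
        stages_config:
          L1: {duration: 3, survival: 0.99}
          L2: {duration: {nbinom: {size: 8, p: 0.8}}, survival: 0.99}
          ...
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise CohortError("simulation config must be a mapping")
    if "stages" in raw:
        order = StageOrder(tuple(raw["stages"]), raw.get("sexing_stage"))
    else:
        order = StageOrder.default()
    durations: dict[str, Duration] = {}
    survival: dict[str, float] = {}
    stages_cfg = raw.get("stages_config", {})
    for s in order.stages:
        entry = stages_cfg.get(s)
        if entry is None:
            raise CohortError(f"stages_config missing stage {s!r}")
        dur = entry.get("duration")
        if isinstance(dur, dict) and "nbinom" in dur:
            nb = dur["nbinom"]
            durations[s] = Duration.negative_binomial(nb["size"], nb["p"])
        elif isinstance(dur, (int, float)):
            durations[s] = Duration.fixed(int(dur))
        else:
            raise CohortError(f"stage {s!r}: duration must be an integer or "
                              f"{{nbinom: {{size, p}}}}")
        survival[s] = float(entry.get("survival", _DEFAULT_SURVIVAL))
    cfg = SimulationConfig(
        stage_order=order,
        n=int(raw.get("n", 100)),
        durations=durations,
        survival=survival,
        female_fraction=float(raw.get("female_fraction", 0.5)),
        total_fecundity=float(raw.get("total_fecundity", 0.0)),
        preoviposition_days=int(raw.get("preoviposition_days", 0)),
        fecundity_peak=int(raw.get("fecundity_peak", 0)),
        fecundity_spread=float(raw.get("fecundity_spread", 1.0)),
        seed=int(raw.get("seed", 0)),
    )
    return cfg.validate()


def write_report(values: dict[str, float], path: PathLike) -> None:
    """Flat ``key = value`` report."""
    lines = [f"{k} = {v}" for k, v in values.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _matrix_frame(mat: np.ndarray, order: StageOrder) -> pd.DataFrame:
    df = pd.DataFrame(mat, columns=list(order.stages))
    df.insert(0, "age_day", np.arange(mat.shape[0]))
    return df


def write_life_table_outputs(result: LifeTableResult, outdir: PathLike) -> None:
    """Write the parameter report plus CSV matrices (s_xj, lx/mx, e_xj, v_xj)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    p = result.params
    write_report({"r": p.r, "lambda": p.lam, "R0": p.R0, "T": p.T},
                 out / "parameters.txt")
    order = result.matrix.stage_order
    _matrix_frame(result.matrix.survival, order).to_csv(out / "sxj.csv", index=False)
    sched = pd.DataFrame({
        "age_day": np.arange(result.schedules.lx.size),
        "lx": result.schedules.lx,
        "mx": result.schedules.mx,
        "lxmx": result.schedules.lxmx,
    })
    sched.to_csv(out / "schedules.csv", index=False)
    _matrix_frame(result.exj, order).to_csv(out / "exj.csv", index=False)
    _matrix_frame(result.vxj, order).to_csv(out / "vxj.csv", index=False)
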