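"""Scenario builders for the three in-silico experiments.

* A **two-group life-history sweep**: one reference group with fixed traits
  (cell C:N ~12, slow turnover, full enzyme investment) competes against a
  second group whose cell C:N (6/9/12 nominal classes), maximum cell size
  (100 or 10 fmol C, i.e. slow/fungal vs fast/bacterial turnover) and enzyme
  investment (12% or 6%) are varied factorially, across initial litter C:N
  from 15 to 95.
* A **three-group substrate-specialist model**: plant degraders (90% of
  enzymes against plant material, 10% against N-rich remains),
  microbial-remains degraders (50/50 against the two necromass pools) and
  fast-growing opportunists producing no enzymes at all, run at litter C:N
  45-75.
* A **uniform-population control**: a single group producing all three
  enzyme classes (allocation 0.7/0.15/0.15).

All scenarios of one comparison share identical initial total carbon (only
litter N varies), which the builders assert.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core_model import (
    COMPOSITIONS,
    ConfigurationError,
    FunctionalGroup,
    SimulationParams,
)
from .scheduler import SimulationResult, run_simulation

__all__ = [
    "Scenario",
    "make_group",
    "build_two_group_sweep",
    "build_three_group_model",
    "build_uniform_population_model",
    "run_scenario",
]

#: nominal cell C:N classes -> macromolecular composition keys
_CN_CLASS = {6: "r-strategist", 9: "generalist", 12: "k-strategist"}

#: default enzyme-class allocation for non-specialist groups (plant : MR-C :
#: MR-N = 7 : 1.5 : 1.5)
GENERALIST_ENZ_RATIO = (0.7, 0.15, 0.15)


@dataclass(frozen=True)
class Scenario:
    """One fully specified model run (groups, params, litter C:N, seed)."""

    name: str
    groups: tuple[FunctionalGroup, ...]
    litter_cn: float
    params: SimulationParams
    seed: int = 0
    metadata: dict = field(default_factory=dict)


def make_group(
    name: str,
    cn_class: int | str,
    mcs: float,
    enz_fract: float,
    enz_ratio: Sequence[float] = GENERALIST_ENZ_RATIO,
    max_cells_per_site: int | None = None,
) -> FunctionalGroup:
    """Build a functional group from a nominal C:N class and life-history.

    ``cn_class`` is 6, 9 or 12 (the nominal cell C:N classes realised by the
    archetypal macromolecular compositions) or a composition key.  Small
    cells (MCS <= 10 fmol C) default to colonies of three per microsite,
    large cells to one.
    """
    key = _CN_CLASS.get(cn_class, cn_class)
    if key not in COMPOSITIONS:
        raise ConfigurationError(f"unknown cell C:N class {cn_class!r}")
    f_dom, f_mrc, f_mrn = COMPOSITIONS[key]
    if max_cells_per_site is None:
        max_cells_per_site = 3 if mcs <= 10 else 1
    return FunctionalGroup(
        name=name, f_dom=f_dom, f_mrc=f_mrc, f_mrn=f_mrn, mcs=mcs,
        max_cells_per_site=max_cells_per_site, enz_fract=enz_fract,
        enz_ratio=tuple(enz_ratio),
    )


def _assert_equal_carbon(scenarios: Sequence[Scenario]) -> None:
    totals = {
        s.params.grid_size ** 2 * s.params.init_plant_c for s in scenarios
    }
    if len(totals) > 1:
        raise ConfigurationError(
            "scenarios of one comparison must share identical initial total C"
        )


def build_two_group_sweep(
    params: SimulationParams | None = None,
    litter_grid: Iterable[float] = range(15, 96, 10),
    seeds: Iterable[int] = range(5),
) -> list[Scenario]:
    """Full factorial of the two-group life-history competition experiment.

    Group 1 is fixed (C:N class 12, MCS 100 fmol C, 12% enzyme investment);
    group 2 varies over C:N class {6, 9, 12} x MCS {100, 10} x enzyme
    investment {12%, 6%}.  With the default litter grid {15, 25, ..., 95}
    and 5 seeds this enumerates 12 x 9 x 5 = 540 runs.
    """
    params = params or SimulationParams.default()
    group1 = make_group("group1", 12, mcs=100.0, enz_fract=0.12)
    scenarios = []
    for cn_class in (6, 9, 12):
        for mcs in (100.0, 10.0):
            for enz_fract in (0.12, 0.06):
                group2 = make_group("group2", cn_class, mcs=mcs, enz_fract=enz_fract)
                label = f"cn{cn_class}_mcs{int(mcs)}_enz{enz_fract:g}"
                for cn_litter in litter_grid:
                    for seed in seeds:
                        scenarios.append(Scenario(
                            name=f"two_group_{label}",
                            groups=(group1, group2),
                            litter_cn=float(cn_litter),
                            params=params,
                            seed=int(seed),
                            metadata={
                                "experiment": "two_group_sweep",
                                "cn_class": cn_class,
                                "mcs": mcs,
                                "enz_fract": enz_fract,
                            },
                        ))
    _assert_equal_carbon(scenarios)
    return scenarios


def three_groups() -> tuple[FunctionalGroup, ...]:
    """The plant-degrader / MR-degrader / opportunist trait bundles."""
    plant_degrader = make_group(
        "plant_degrader", 12, mcs=100.0, enz_fract=0.12, enz_ratio=(0.9, 0.0, 0.1)
    )
    mr_degrader = make_group(
        "mr_degrader", 12, mcs=100.0, enz_fract=0.12, enz_ratio=(0.0, 0.5, 0.5)
    )
    opportunist = make_group(
        "opportunist", 6, mcs=10.0, enz_fract=0.0
    )
    return (plant_degrader, mr_degrader, opportunist)


def build_three_group_model(
    litter_cn: float,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> Scenario:
    """The substrate-specific three-group scenario at one litter C:N.

    Plant degraders put 90% of enzyme production into plant-material
    degradation and 10% into N-rich remains; microbial-remains degraders
    split theirs 50/50 over the two necromass pools; opportunists are
    fast-growing cheats with no enzyme production.  Runs stop at 90% mass
    loss.  The default litter C:N set of the experiment is {45, 55, 65, 75}.
    """
    params = params or SimulationParams.default()
    return Scenario(
        name=f"three_group_cn{litter_cn:g}",
        groups=three_groups(),
        litter_cn=float(litter_cn),
        params=params,
        seed=seed,
        metadata={"experiment": "three_group"},
    )


def build_uniform_population_model(
    litter_cn: float,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> Scenario:
    """The one-group control: all microbes identical, producing all enzymes.

    Uses the slow, C:N-class-12 trait bundle with the generalist enzyme
    allocation (0.7, 0.15, 0.15); contrasted against the three-group model
    to isolate the effect of substrate-specific functional diversity.
    """
    params = params or SimulationParams.default()
    uniform = make_group("uniform", 12, mcs=100.0, enz_fract=0.12)
    return Scenario(
        name=f"uniform_cn{litter_cn:g}",
        groups=(uniform,),
        litter_cn=float(litter_cn),
        params=params,
        seed=seed,
        metadata={"experiment": "uniform_population"},
    )


def run_scenario(scenario: Scenario, **kwargs) -> SimulationResult:
    """Execute one scenario via the scheduler; metadata is passed through."""
    result = run_simulation(
        scenario.params, scenario.groups, scenario.litter_cn, scenario.seed,
        **kwargs,
    )
    result.metadata.update({"scenario": scenario.name, **scenario.metadata})
    return result
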