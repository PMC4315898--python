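"""Reference computations of the headline emergent quantities.

These helpers run the calibrated default scenarios at the analysis scale
(50x50 grid, four replicate seeds per condition) and distil the quantities
the simulator is judged by: late-decay grid DOM C:N and community CUE of the
three-functional-group model, the one-group control's DOM C:N response to
litter stoichiometry, and the plant-degrader : MR-degrader biomass ratio at
50% C loss.  Both the acceptance script and the acceptance test suite are
thin wrappers over this module, so the numbers they report are recomputed
from scratch by running the simulator.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from . import observables as obs
from .config import default_params
from .experiments import (
    build_three_group_model,
    build_uniform_population_model,
    run_scenario,
)

__all__ = ["run_condition", "emergent_summary"]

#: analysis scale used for the emergent-behaviour evaluation
GRID_SIZE = 50
N_SEEDS = 4
THREE_GROUP_LITTER = (45.0, 55.0, 65.0, 75.0)
UNIFORM_LITTER = (45.0, 75.0)


def _analysis_params(steps_max: int = 8000):
    return dataclasses.replace(
        default_params(), grid_size=GRID_SIZE, steps_max=steps_max
    )


def run_condition(kind: str, litter_cn: float, seed: int,
                  steps_max: int = 8000) -> dict[str, float]:
    """Run one scenario to 90% mass loss and summarise it.

    ``kind`` is ``"three"`` (substrate-specific three-group model) or
    ``"uniform"`` (one-group control).  Returns late-decay means (last 20%
    of steps) of DOM C:N and per-step CCUE, the cumulative CCUE, and -- for
    the three-group model -- the plant:MR-degrader biomass ratio at the
    interpolated time of 50% C loss.
    """
    params = _analysis_params(steps_max)
    build = {"three": build_three_group_model,
             "uniform": build_uniform_population_model}[kind]
    scenario = build(litter_cn, params=params, seed=seed)
    result = run_scenario(scenario)
    rec = result.records
    # late-decay CCUE: the community CUE formula applied to the ledger
    # increments over the last 20% of steps (flux-weighted, so famine steps
    # with negligible uptake do not dominate the estimate)
    n = len(rec)
    i0 = n - max(1, int(round(0.2 * n))) - 1
    du = rec["u_doc"].iloc[-1] - rec["u_doc"].iloc[i0]
    dr = rec["respired_c"].iloc[-1] - rec["respired_c"].iloc[i0]
    dp = rec["p_enz"].iloc[-1] - rec["p_enz"].iloc[i0]
    out = {
        "litter_cn": litter_cn,
        "seed": float(seed),
        "steps": float(result.metadata["steps_run"]),
        "mass_loss": float(rec["mass_loss"].iloc[-1]),
        "dom_cn_late": obs.late_mean(rec, "dom_cn"),
        "ccue_late": obs.ccue(du, dr, dp) if du > 0 else np.nan,
        "ccue_step_late": obs.late_mean(rec, "ccue_step"),
        "ccue_cum": float(rec["ccue_cum"].iloc[-1]),
        "decay_k": obs.decay_rate_k(rec),
    }
    if kind == "three":
        t50 = obs.time_of_mass_loss(rec, 0.5)
        if np.isfinite(t50):
            pd_b = obs.interpolate_at(rec, "biomass_c_plant_degrader", t50)
            mr_b = obs.interpolate_at(rec, "biomass_c_mr_degrader", t50)
            out["ratio50"] = pd_b / mr_b if mr_b > 0 else np.inf
        else:
            out["ratio50"] = np.nan
    return out


def emergent_summary(
    seeds: Iterable[int],
    three_litter: Iterable[float] = THREE_GROUP_LITTER,
    uniform_litter: Iterable[float] = UNIFORM_LITTER,
    progress=None,
) -> dict:
    """Run the full emergent-behaviour evaluation and aggregate it.

    Returns a dict with the per-run table (``runs``) and the aggregated
    headline quantities keyed by descriptive names.
    """
    rows = []
    for cn in three_litter:
        for seed in seeds:
            row = {"kind": "three", **run_condition("three", cn, seed)}
            rows.append(row)
            if progress:
                progress(f"three-group litter C:N {cn:g} seed {seed} done")
    for cn in uniform_litter:
        for seed in seeds:
            row = {"kind": "uniform", **run_condition("uniform", cn, seed)}
            rows.append(row)
            if progress:
                progress(f"uniform litter C:N {cn:g} seed {seed} done")
    runs = pd.DataFrame(rows)
    three = runs[runs["kind"] == "three"]
    uni = runs[runs["kind"] == "uniform"]

    by_cn = three.groupby("litter_cn")["dom_cn_late"].mean()
    uni_by_cn = uni.groupby("litter_cn")["dom_cn_late"].mean()
    summary = {
        "three_group_dom_cn_late": float(by_cn.mean()),
        "three_group_dom_cn_spread": float(by_cn.max() - by_cn.min()),
        "uniform_dom_cn_spread": float(uni_by_cn.max() - uni_by_cn.min()),
        "three_group_ccue_late": float(
            three.groupby("litter_cn")["ccue_late"].mean().mean()
        ),
        "uniform_dom_cn_45": float(uni_by_cn.get(45.0, np.nan)),
        "uniform_dom_cn_75": float(uni_by_cn.get(75.0, np.nan)),
        "ratio50_cn55": float(
            three[three["litter_cn"] == 55.0]["ratio50"].mean()
        ),
        "ratio50_cn75": float(
            three[three["litter_cn"] == 75.0]["ratio50"].mean()
        ),
    }
    return {"runs": runs, "summary": summary}
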