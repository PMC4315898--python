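"""Mortality, necromass partitioning, cell division and colonisation.

Cells die stochastically ("catastrophic death", a proxy for predation and
disturbance, with probability inversely proportional to the group's maximum
cell size) or deterministically by starvation when biomass falls below a
minimum fraction of MCS.  A dead cell's macromolecular components are routed
to the site's substrate pools: solubles to DOM, C-rich compounds to MR-C,
N-rich compounds to MR-N, each with its component stoichiometry.

Cells reaching their group's maximum cell size divide; the daughter fills a
free colony slot at the parent's site, else an empty neighbouring site, else
may invade an occupied neighbour with a small probability (killing the
residents).  Microbes are otherwise immobile: occupancy changes only through
division, invasion and death.
"""

from __future__ import annotations

import numpy as np

from .core_model import FunctionalGroup, SimState, SimulationParams

__all__ = [
    "group_mortality_prob",
    "apply_mortality",
    "partition_necromass",
    "divide_and_colonise",
]

_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_VON_NEUMANN = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def group_mortality_prob(group: FunctionalGroup, params: SimulationParams) -> float:
    """Per-step catastrophic-death probability of one cell of this group.

    Unless the group carries an explicit override, mortality scales inversely
    with maximum cell size: ``p = mortality_ref * mcs_ref / mcs`` (clamped to
    [0, 1]), so small fast-turnover cells die more often.
    """
    if group.mortality_prob is not None:
        return min(max(group.mortality_prob, 0.0), 1.0)
    return min(max(params.mortality_ref * params.mcs_ref / group.mcs, 0.0), 1.0)


def partition_necromass(
    state: SimState, i: int, j: int, biomass_c: float, group: FunctionalGroup
) -> None:
    """Distribute a dead cell's C and N over the site's substrate pools.

    Carbon follows the group's macromolecular composition; each component
    carries N at its fixed component C:N, so the total N transferred equals
    ``biomass_c / group.cell_cn`` exactly.
    """
    comps = group.comps
    state.dom_c[i, j] += group.f_dom * biomass_c
    state.dom_n[i, j] += group.f_dom * biomass_c / comps.cn_dom_component
    state.mrc_c[i, j] += group.f_mrc * biomass_c
    state.mrc_n[i, j] += group.f_mrc * biomass_c / comps.cn_mrc
    state.mrn_c[i, j] += group.f_mrn * biomass_c
    state.mrn_n[i, j] += group.f_mrn * biomass_c / comps.cn_mrn


def _partition_bulk(state: SimState, dead_by_group: np.ndarray) -> None:
    """Vectorised necromass partitioning of per-site dead biomass per group."""
    for g, grp in enumerate(state.groups):
        d = dead_by_group[g]
        if not d.any():
            continue
        comps = grp.comps
        state.dom_c += grp.f_dom * d
        state.dom_n += grp.f_dom * d / comps.cn_dom_component
        state.mrc_c += grp.f_mrc * d
        state.mrc_n += grp.f_mrc * d / comps.cn_mrc
        state.mrn_c += grp.f_mrn * d
        state.mrn_n += grp.f_mrn * d / comps.cn_mrn


def apply_mortality(
    state: SimState, params: SimulationParams, rng: np.random.Generator | None = None
) -> int:
    """Apply stochastic and starvation mortality across the grid (in place).

    Returns the number of deaths.  Dead biomass is partitioned into the
    site's substrate pools; sites whose colony is wiped out become empty.
    """
    rng = rng or state.rng
    b = state.biomass
    alive = b > 0
    n_groups = len(state.groups)
    p_lookup = np.array(
        [group_mortality_prob(g, params) for g in state.groups] + [0.0]
    )
    mcs_lookup = np.array([g.mcs for g in state.groups] + [np.inf])
    idx = np.where(state.group >= 0, state.group, n_groups)
    p_site = p_lookup[idx]
    mcs_site = mcs_lookup[idx]

    draws = rng.random(b.shape)
    catastrophic = alive & (draws < p_site)
    starved = alive & (b < params.starvation_min * mcs_site)
    dead = catastrophic | starved
    n_dead = int(dead.sum())
    if n_dead:
        dead_by_group = np.zeros((n_groups,) + state.shape)
        dead_b = np.where(dead, b, 0.0).sum(axis=0)
        for g in range(n_groups):
            dead_by_group[g] = np.where(state.group == g, dead_b, 0.0)
        _partition_bulk(state, dead_by_group)
        b[dead] = 0.0
        state.group[b.sum(axis=0) == 0] = -1
    return n_dead


def _neighbours(params: SimulationParams) -> list[tuple[int, int]]:
    return _MOORE if params.colonise_neighbourhood == "moore" else _VON_NEUMANN


def divide_and_colonise(
    state: SimState, params: SimulationParams, rng: np.random.Generator | None = None
) -> dict[str, int]:
    """Divide every cell that reached its group's maximum size (in place).

    The daughter cell (half the parent's biomass) goes, in order of
    preference, to (1) a free colony slot at the parent's site, (2) a
    uniformly chosen empty neighbouring site, (3) with probability
    ``invade_prob``, a uniformly chosen occupied neighbouring site whose
    residents then die and are partitioned to necromass.  If all three fail
    the division is deferred: the parent stays at MCS and the excess C is
    respired as overflow (its stoichiometric N share is mineralised).

    Returns counters: divisions, colonisations, invasions, deferred.
    """
    rng = rng or state.rng
    b = state.biomass
    h, w = state.shape
    n_groups = len(state.groups)
    mcs_lookup = np.array([g.mcs for g in state.groups] + [np.inf])
    idx = np.where(state.group >= 0, state.group, n_groups)
    mcs_site = mcs_lookup[idx]

    cand = np.argwhere(b >= mcs_site[None, :, :])
    counters = {"divisions": 0, "colonisations": 0, "invasions": 0, "deferred": 0}
    if len(cand) == 0:
        return counters
    offsets = _neighbours(params)
    order = rng.permutation(len(cand))
    for k in order:
        s, i, j = cand[k]
        g = int(state.group[i, j])
        if g < 0:
            continue   # colony was wiped out by an earlier invasion
        grp = state.groups[g]
        biomass = b[s, i, j]
        if biomass < grp.mcs:
            continue
        half = biomass / 2.0

        # (1) free slot in the parent's own colony
        placed = False
        for slot in range(grp.max_cells_per_site):
            if b[slot, i, j] == 0.0:
                b[s, i, j] = half
                b[slot, i, j] = half
                placed = True
                break
        if placed:
            counters["divisions"] += 1
            continue

        empty, occupied = [], []
        for di, dj in offsets:
            ni, nj = (i + di) % h, (j + dj) % w
            if state.group[ni, nj] < 0:
                empty.append((ni, nj))
            else:
                occupied.append((ni, nj))

        if empty:
            ni, nj = empty[rng.integers(len(empty))]
            b[s, i, j] = half
            state.group[ni, nj] = g
            b[0, ni, nj] = half
            counters["divisions"] += 1
            counters["colonisations"] += 1
            continue

        # (3) invasion of one uniformly chosen occupied neighbour
        invaded = False
        if occupied:
            ni, nj = occupied[rng.integers(len(occupied))]
            if rng.random() < params.invade_prob:
                owner = state.groups[int(state.group[ni, nj])]
                victim_b = float(b[:, ni, nj].sum())
                if victim_b > 0:
                    partition_necromass(state, ni, nj, victim_b, owner)
                b[:, ni, nj] = 0.0
                state.group[ni, nj] = g
                b[s, i, j] = half
                b[0, ni, nj] = half
                counters["divisions"] += 1
                counters["invasions"] += 1
                invaded = True
        if invaded:
            continue

        # deferred: stay at MCS, excess C is overflow respiration and the
        # stoichiometrically coupled N is mineralised
        excess = biomass - grp.mcs
        if excess > 0:
            b[s, i, j] = grp.mcs
            state.ledgers.resp_overflow += excess
            state.ledgers.mineralised_n += excess / grp.cell_cn
            state.din[i, j] += excess / grp.cell_cn
        counters["deferred"] += 1
    return counters
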