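"""Shared fixtures: small parameter sets, trait bundles, tiny grids."""

import dataclasses

import numpy as np
import pytest

import microstoich as ms


@pytest.fixture(scope="session")
def params():
    """Shipped defaults, unmodified."""
    return ms.default_params()


@pytest.fixture()
def small_params(params):
    """Defaults on a small grid with quiet demography, for unit tests."""
    return dataclasses.replace(
        params, grid_size=10, init_occupancy=0.1, steps_max=100
    )


@pytest.fixture(scope="session")
def k_group():
    return ms.make_group("k", 12, mcs=100.0, enz_fract=0.12)


@pytest.fixture(scope="session")
def r_group():
    return ms.make_group("r", 6, mcs=10.0, enz_fract=0.06)


@pytest.fixture(scope="session")
def cn10_group():
    """A group whose derived cell C:N is exactly 10 (f = 0, 15/29, 14/29)."""
    return ms.FunctionalGroup(
        name="cn10", f_dom=0.0, f_mrc=15.0 / 29.0, f_mrn=14.0 / 29.0,
        mcs=100.0, enz_fract=0.12,
    )


def make_empty_state(params, groups, litter_cn=50.0, seed=0):
    """A grid with no microbes (occupancy zero)."""
    p = dataclasses.replace(params, init_occupancy=0.0)
    return ms.init_litter_grid(p, litter_cn, groups, seed)


@pytest.fixture()
def empty_state(small_params, k_group):
    return make_empty_state(small_params, [k_group])


def place_cell(state, i, j, group_id, biomass):
    """Drop one cell into an (empty) site, fixing totals afterwards."""
    state.group[i, j] = group_id
    free = np.argmin(state.biomass[:, i, j])
    state.biomass[free, i, j] = biomass
    grp = state.groups[group_id]
    state.initial_c += biomass
    state.initial_n += biomass / grp.cell_cn
    return state
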