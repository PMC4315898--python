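"""Mortality, necromass routing, division, colonisation and invasion."""

import dataclasses

import numpy as np
import pytest

import microstoich as ms
from microstoich.demography import (
    apply_mortality,
    divide_and_colonise,
    group_mortality_prob,
    partition_necromass,
)
from tests.conftest import make_empty_state, place_cell


class TestMortality:
    def test_no_mortality_no_deaths(self, small_params, k_group):
        p = dataclasses.replace(small_params, mortality_ref=0.0, init_occupancy=0.2)
        state = ms.init_litter_grid(p, 50.0, [k_group], seed=0)
        assert apply_mortality(state, p) == 0

    def test_certain_death_kills_everyone(self, small_params):
        doomed = ms.make_group("doomed", 12, mcs=100.0, enz_fract=0.12)
        doomed = dataclasses.replace(doomed, mortality_prob=1.0)
        p = dataclasses.replace(small_params, init_occupancy=0.3)
        state = ms.init_litter_grid(p, 50.0, [doomed], seed=0)
        apply_mortality(state, p)
        assert state.biomass.sum() == 0.0
        assert (state.group == -1).all()

    def test_starvation_below_minimum_biomass(self, small_params, k_group):
        p = dataclasses.replace(small_params, mortality_ref=0.0)
        state = make_empty_state(p, [k_group])
        place_cell(state, 1, 1, 0, 0.5 * p.starvation_min * k_group.mcs)
        place_cell(state, 3, 3, 0, 2.0 * p.starvation_min * k_group.mcs)
        assert apply_mortality(state, p) == 1
        assert state.group[1, 1] == -1 and state.group[3, 3] == 0

    def test_death_count_is_binomial(self, params, k_group):
        """p=0.02, 1000 cells: mean deaths 20 within 3 sigma over seeds."""
        grp = dataclasses.replace(k_group, mortality_prob=0.02)
        p = dataclasses.replace(params, grid_size=40, init_occupancy=0.625)
        counts = []
        for seed in range(30):
            state = ms.init_litter_grid(p, 50.0, [grp], seed=seed)
            assert (state.group == 0).sum() == 1000
            counts.append(apply_mortality(state, p))
        se = np.sqrt(1000 * 0.02 * 0.98)
        assert abs(np.mean(counts) - 20.0) < 3 * se / np.sqrt(len(counts))

    def test_smaller_cells_die_more(self, params, k_group, r_group):
        assert group_mortality_prob(r_group, params) == pytest.approx(
            10 * group_mortality_prob(k_group, params)
        )


class TestPartitionNecromass:
    def test_k_strategist_component_arithmetic(self, small_params, k_group):
        """B=100: DOM +(6, 0.4), MR-C +(57, 0.38), MR-N +(37, 7.4);
        total N = 100 / 12.22."""
        state = make_empty_state(small_params, [k_group])
        partition_necromass(state, 0, 0, 100.0, k_group)
        assert state.dom_c[0, 0] - small_params.init_dom_c == pytest.approx(6.0)
        assert state.mrc_c[0, 0] == pytest.approx(57.0)
        assert state.mrn_c[0, 0] == pytest.approx(37.0)
        n_added = (
            (state.dom_n[0, 0] - small_params.init_dom_c / small_params.init_dom_cn)
            + state.mrc_n[0, 0] + state.mrn_n[0, 0]
        )
        assert n_added == pytest.approx(6 / 15 + 57 / 150 + 37 / 5, rel=1e-12)
        assert n_added == pytest.approx(100.0 / k_group.cell_cn, rel=1e-12)

    def test_zero_biomass_noop(self, small_params, k_group):
        state = make_empty_state(small_params, [k_group])
        before = state.mrc_c.copy()
        partition_necromass(state, 2, 2, 0.0, k_group)
        assert np.array_equal(before, state.mrc_c)


class TestDivideAndColonise:
    def fixture_3x3(self, params, group, biomass):
        p = dataclasses.replace(params, grid_size=3, init_occupancy=0.0,
                                mortality_ref=0.0)
        state = make_empty_state(p, [group])
        place_cell(state, 1, 1, 0, biomass)
        return state, p

    def test_below_mcs_no_division(self, params, k_group):
        state, p = self.fixture_3x3(params, k_group, 99.9)
        counters = divide_and_colonise(state, p)
        assert counters["divisions"] == 0
        assert state.biomass[0, 1, 1] == 99.9

    def test_division_colonises_one_neighbour(self, params, k_group):
        state, p = self.fixture_3x3(params, k_group, 100.0)
        counters = divide_and_colonise(state, p)
        assert counters == {"divisions": 1, "colonisations": 1,
                            "invasions": 0, "deferred": 0}
        occupied = np.argwhere(state.group == 0)
        assert len(occupied) == 2
        assert state.biomass.sum() == pytest.approx(100.0)
        assert sorted(state.biomass[state.biomass > 0]) == [50.0, 50.0]
        # daughter landed in the Moore neighbourhood of the parent
        others = [tuple(ij) for ij in occupied if tuple(ij) != (1, 1)]
        di, dj = others[0]
        assert max(abs(di - 1), abs(dj - 1)) == 1

    def test_own_colony_slot_filled_first(self, params, r_group):
        p = dataclasses.replace(params, grid_size=3, init_occupancy=0.0,
                                mortality_ref=0.0)
        state = make_empty_state(p, [r_group])
        place_cell(state, 1, 1, 0, r_group.mcs)
        divide_and_colonise(state, p)
        assert (state.group == 0).sum() == 1     # stayed in-site
        assert sorted(state.biomass[:, 1, 1])[-2:] == [5.0, 5.0]

    def test_invasion_frequency_matches_probability(self, params, k_group):
        """All neighbours occupied: invasion succeeds at ~0.01."""
        rng = np.random.default_rng(123)
        n_trials, successes = 4000, 0
        p = dataclasses.replace(params, grid_size=3, init_occupancy=0.0,
                                mortality_ref=0.0)
        for _ in range(n_trials):
            state = make_empty_state(p, [k_group])
            for i in range(3):
                for j in range(3):
                    place_cell(state, i, j, 0, 60.0)
            state.biomass[0, 1, 1] = 100.0
            state.rng = rng
            counters = divide_and_colonise(state, p, rng)
            successes += counters["invasions"]
            assert counters["invasions"] + counters["deferred"] == 1
        se = np.sqrt(n_trials * 0.01 * 0.99)
        assert abs(successes - n_trials * 0.01) < 4 * se

    def test_deferred_division_respires_excess_as_overflow(self, params, k_group):
        p = dataclasses.replace(params, grid_size=3, init_occupancy=0.0,
                                mortality_ref=0.0, invade_prob=0.0)
        state = make_empty_state(p, [k_group])
        for i in range(3):
            for j in range(3):
                place_cell(state, i, j, 0, 60.0)
        state.biomass[0, 1, 1] = 112.0
        counters = divide_and_colonise(state, p)
        assert counters["deferred"] == 1
        assert state.biomass[0, 1, 1] == k_group.mcs
        assert state.ledgers.resp_overflow == pytest.approx(12.0)
        assert state.din[1, 1] == pytest.approx(
            p.init_din + 12.0 / k_group.cell_cn
        )

    def test_conservation_through_mortality_and_division(self, small_params, k_group):
        p = dataclasses.replace(small_params, init_occupancy=0.3)
        state = ms.init_litter_grid(p, 50.0, [k_group], seed=5)
        state.biomass[state.biomass > 0] = k_group.mcs  # everyone divides
        state.initial_c = ms.total_carbon(state)
        state.initial_n = ms.total_nitrogen_with(state, p.enzyme_cn)
        apply_mortality(state, p)
        divide_and_colonise(state, p)
        ms.check_conservation(state, p)

    def test_occupancy_changes_only_via_demography(self, small_params, k_group):
        """Microbes are immobile: diffusion and physiology never move cells."""
        p = dataclasses.replace(small_params, init_occupancy=0.2)
        state = ms.init_litter_grid(p, 50.0, [k_group], seed=2)
        occ_before = state.group.copy()
        from microstoich.enzymatics import age_enzymes, degrade_pools
        from microstoich.physiology import allocate_and_balance, compute_uptake
        from microstoich.transport import diffuse_and_leach
        degrade_pools(state, p)
        u_c, u_n = compute_uptake(state, p)
        allocate_and_balance(state, p, u_c, u_n)
        age_enzymes(state, p)
        diffuse_and_leach(state, p)
        assert np.array_equal(state.group, occ_before)
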