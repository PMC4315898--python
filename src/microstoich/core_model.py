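"""Domain types and grid initialisation for the microsite decomposition model.

The model world is a 2-D lattice of *microsites* (10 um cubes of decomposing
litter).  Each microsite carries three complex substrate pools -- native plant
material and two classes of microbial necromass (C-rich ``MR-C``, C:N 150, and
N-rich ``MR-N``, C:N 5) -- plus dissolved organic matter (DOM), dissolved
inorganic N (DIN) and three extracellular-enzyme pools, and can host a small
colony of cells belonging to exactly one microbial functional group.

State is stored struct-of-arrays (one numpy array per pool) so a whole time
step is a handful of vectorised array operations; :class:`Microsite` is a
read-only per-site view used for inspection and in unit tests.

All carbon quantities are femtomol C per microsite; nitrogen is fmol N.
One time step represents 3 hours.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ComponentStoichiometry",
    "FunctionalGroup",
    "SimulationParams",
    "Ledgers",
    "SimState",
    "Microsite",
    "derive_cell_cn",
    "init_litter_grid",
    "total_carbon",
    "total_nitrogen_with",
    "check_conservation",
]

#: indices of the three enzyme classes / complex substrate pools
PLANT, MRC, MRN = 0, 1, 2


class InvalidTraitError(ValueError):
    """Raised when functional-group trait fractions are inconsistent."""


class ConfigurationError(ValueError):
    """Raised for inconsistent scenario / parameter configuration."""


class StateCorruptionError(RuntimeError):
    """Raised when a state invariant (non-negativity, conservation) is broken."""


@dataclass(frozen=True)
class ComponentStoichiometry:
    """C:N mass ratios of the three macromolecular cell components.

    These are fixed constants of the model: cell solubles (sugars, amino
    acids, small peptides) at C:N 15, C-rich structural/storage compounds
    (cell walls, lipids, carbohydrates) at C:N 150, and N-rich macromolecules
    (proteins, DNA, RNA) at C:N 5.
    """

    cn_dom_component: float = 15.0
    cn_mrc: float = 150.0
    cn_mrn: float = 5.0

    def __post_init__(self) -> None:
        if min(self.cn_dom_component, self.cn_mrc, self.cn_mrn) <= 0:
            raise InvalidTraitError("component C:N ratios must be positive")


def derive_cell_cn(
    f_dom: float,
    f_mrc: float,
    f_mrn: float,
    comps: ComponentStoichiometry = ComponentStoichiometry(),
) -> float:
    """Whole-cell C:N from the macromolecular composition of the cell.

    ``f_dom``, ``f_mrc``, ``f_mrn`` are the fractions of cell *carbon* held in
    the soluble, C-rich and N-rich components.  With component C:N ratios
    ``cn_i``, one unit of cell C carries ``sum(f_i / cn_i)`` units of N, so

        cell C:N = 1 / (f_dom/15 + f_mrc/150 + f_mrn/5)

    at the default component stoichiometry.
    """
    fracs = (f_dom, f_mrc, f_mrn)
    if any(f < -1e-12 or f > 1 + 1e-12 for f in fracs):
        raise InvalidTraitError(f"component fractions must lie in [0, 1]: {fracs}")
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise InvalidTraitError(
            f"component fractions must sum to 1 (got {sum(fracs)!r})"
        )
    n_per_c = (
        f_dom / comps.cn_dom_component + f_mrc / comps.cn_mrc + f_mrn / comps.cn_mrn
    )
    return 1.0 / n_per_c


@dataclass(frozen=True)
class FunctionalGroup:
    """Immutable trait bundle defining one microbial functional group.

    Parameters
    ----------
    name:
        Label used in trait tables and output records.
    f_dom, f_mrc, f_mrn:
        Fractions of cell carbon in the soluble / C-rich / N-rich
        macromolecular components (sum to 1).  They fix the whole-cell C:N
        and how necromass is partitioned on death.
    mcs:
        Maximum cell size (fmol C); cells divide on reaching it.  Small MCS
        means fast surface-limited growth and high stochastic mortality
        (r-strategist); large MCS the opposite (K-strategist).
    max_cells_per_site:
        Colony capacity of one microsite for this group.
    enz_fract:
        Fraction of post-maintenance C uptake invested in extracellular
        enzyme production.
    enz_ratio:
        Allocation of enzyme production across the three enzyme classes
        (plant, MR-C, MR-N); sums to 1.
    mortality_prob:
        Optional explicit per-step catastrophic-death probability.  When
        ``None`` it is derived as ``mortality_ref * mcs_ref / mcs`` (mortality
        inversely proportional to maximum cell size).
    """

    name: str
    f_dom: float
    f_mrc: float
    f_mrn: float
    mcs: float
    max_cells_per_site: int = 1
    enz_fract: float = 0.12
    enz_ratio: tuple[float, float, float] = (0.7, 0.15, 0.15)
    mortality_prob: float | None = None
    comps: ComponentStoichiometry = ComponentStoichiometry()
    cell_cn: float = field(init=False)

    def __post_init__(self) -> None:
        cn = derive_cell_cn(self.f_dom, self.f_mrc, self.f_mrn, self.comps)
        object.__setattr__(self, "cell_cn", cn)
        object.__setattr__(self, "enz_ratio", tuple(float(x) for x in self.enz_ratio))
        if abs(sum(self.enz_ratio) - 1.0) > 1e-9:
            raise InvalidTraitError(f"enz_ratio must sum to 1: {self.enz_ratio}")
        if any(x < 0 for x in self.enz_ratio):
            raise InvalidTraitError(f"enz_ratio entries must be >= 0: {self.enz_ratio}")
        if not 0.0 <= self.enz_fract <= 1.0:
            raise InvalidTraitError(f"enz_fract must lie in [0, 1]: {self.enz_fract}")
        if self.mcs <= 0:
            raise InvalidTraitError("mcs must be positive")
        if self.max_cells_per_site < 1:
            raise InvalidTraitError("max_cells_per_site must be >= 1")

    def necromass_fractions(self) -> tuple[float, float, float]:
        """(DOM, MR-C, MR-N) carbon fractions of a dead cell."""
        return (self.f_dom, self.f_mrc, self.f_mrn)


# Macromolecular compositions (fraction of cell C in DOM / MR-C / MR-N
# components) of the three archetypal life-history strategies.  The resulting
# whole-cell C:N ratios are 6.21, 9.03 and 12.22.
COMPOSITIONS: dict[str, tuple[float, float, float]] = {
    "r-strategist": (0.06, 0.16, 0.78),
    "generalist": (0.06, 0.42, 0.52),
    "k-strategist": (0.06, 0.57, 0.37),
}


@dataclass
class SimulationParams:
    """Every rate constant of the simulator, with documented defaults.

    Defaults are loaded from the version-controlled parameter file shipped
    with the package (``data/default_params.yaml``); construct via
    :meth:`default` or :func:`microstoich.config.load_config`.  Quantities are
    per 3-h time step and per microsite unless noted.
    """

    # enzymatic degradation (per enzyme class: plant, MR-C, MR-N)
    vmax: tuple[float, float, float] = (0.55, 2.0, 1.5)
    km: tuple[float, float, float] = (10.0, 10.0, 10.0)
    # microbial physiology
    uptake_coeff: float = 0.2          # max DOC uptake per (fmol C)^(2/3) per step
    surface_exponent: float = 2.0 / 3.0
    maintenance_fract: float = 0.0017   # C respired per biomass C per step
    resp_growth: float = 0.2           # overhead respiration per C grown
    resp_enz: float = 0.2              # overhead respiration per enzyme C produced
    constitutive_fract: float = 0.1    # paper-fixed: 1/10 of maximal enzyme production
    enzyme_cn: float = 5.0             # enzymes are protein: C:N 5
    enzyme_lifetime: float = 20.0      # mean steps before denaturation into MR-N
    # transport
    diff_dom: float = 0.1              # fraction of site DOM exchanged per step
    diff_din: float = 0.9
    leach_fract: float = 0.002         # fraction of diffusing material lost
    # demography
    mortality_ref: float = 0.001       # per-step death prob at mcs == mcs_ref
    mcs_ref: float = 100.0
    starvation_min: float = 0.05        # death below this fraction of MCS
    invade_prob: float = 0.01          # paper-fixed
    colonise_neighbourhood: str = "moore"   # "moore" or "von_neumann"
    # initial state
    grid_size: int = 100               # paper-fixed: 100 x 100 microsites
    init_plant_c: float = 3000.0       # fmol C per microsite
    init_occupancy: float = 0.05       # fraction of sites seeded per group
    init_din: float = 1.0              # fmol N per microsite
    init_dom_c: float = 5.0           # fmol C per microsite
    init_dom_cn: float = 15.0
    init_enzyme_c: float = 0.0         # fmol enzyme C per microsite (per 3 classes)
    # run control
    steps_max: int = 20000
    mass_loss_stop: float = 0.9
    step_hours: float = 3.0            # paper-fixed
    comps: ComponentStoichiometry = ComponentStoichiometry()

    def __post_init__(self) -> None:
        self.vmax = tuple(float(v) for v in self.vmax)
        self.km = tuple(float(k) for k in self.km)
        if len(self.vmax) != 3 or len(self.km) != 3:
            raise ConfigurationError("vmax and km must have three entries")
        scalars = {
            "uptake_coeff": self.uptake_coeff,
            "maintenance_fract": self.maintenance_fract,
            "resp_growth": self.resp_growth,
            "resp_enz": self.resp_enz,
            "enzyme_cn": self.enzyme_cn,
            "enzyme_lifetime": self.enzyme_lifetime,
            "mortality_ref": self.mortality_ref,
            "mcs_ref": self.mcs_ref,
            "init_plant_c": self.init_plant_c,
            "init_din": self.init_din,
            "init_dom_c": self.init_dom_c,
            "init_enzyme_c": self.init_enzyme_c,
        }
        for name, val in scalars.items():
            if val < 0:
                raise ConfigurationError(f"{name} must be >= 0 (got {val})")
        fractions = {
            "maintenance_fract": self.maintenance_fract,
            "constitutive_fract": self.constitutive_fract,
            "diff_dom": self.diff_dom,
            "diff_din": self.diff_din,
            "leach_fract": self.leach_fract,
            "starvation_min": self.starvation_min,
            "invade_prob": self.invade_prob,
            "init_occupancy": self.init_occupancy,
            "mass_loss_stop": self.mass_loss_stop,
        }
        for name, val in fractions.items():
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1] (got {val})")
        if self.colonise_neighbourhood not in ("moore", "von_neumann"):
            raise ConfigurationError(
                f"unknown colonise_neighbourhood {self.colonise_neighbourhood!r}"
            )
        if self.grid_size < 1:
            raise ConfigurationError("grid_size must be >= 1")

    @classmethod
    def default(cls, **overrides) -> "SimulationParams":
        """The shipped default parameter set, with optional field overrides."""
        from .config import default_params

        p = default_params()
        if overrides:
            p = dataclasses.replace(p, **overrides)
        return p


@dataclass
class Ledgers:
    """Cumulative whole-grid flux accounts (fmol C or N since t=0).

    Respiration is split by pathway so community CUE and its components can
    be reconstructed exactly from the ledger alone.
    """

    resp_maintenance: float = 0.0
    resp_growth: float = 0.0
    resp_enzyme: float = 0.0
    resp_overflow: float = 0.0
    leached_c: float = 0.0
    leached_n: float = 0.0
    mineralised_n: float = 0.0
    immobilised_n: float = 0.0
    enzyme_c_produced: float = 0.0   # P_ENZ
    doc_uptake: float = 0.0          # U_DOC

    @property
    def respired_c(self) -> float:
        """Total respired C (R)."""
        return (
            self.resp_maintenance
            + self.resp_growth
            + self.resp_enzyme
            + self.resp_overflow
        )

    def copy(self) -> "Ledgers":
        return dataclasses.replace(self)


@dataclass
class SimState:
    """Full simulator state: pool fields, colonies, ledgers, RNG.

    Arrays are shape ``(H, W)`` except ``enzymes`` (``(3, H, W)``) and
    ``biomass`` (``(S, H, W)`` with ``S`` colony slots; 0 marks an empty
    slot).  ``group[i, j]`` is the resident group index or -1.
    """

    plant_c: np.ndarray
    plant_n: np.ndarray
    mrc_c: np.ndarray
    mrc_n: np.ndarray
    mrn_c: np.ndarray
    mrn_n: np.ndarray
    dom_c: np.ndarray
    dom_n: np.ndarray
    din: np.ndarray
    enzymes: np.ndarray
    group: np.ndarray
    biomass: np.ndarray
    groups: tuple[FunctionalGroup, ...]
    rng: np.random.Generator
    t: int = 0
    ledgers: Ledgers = field(default_factory=Ledgers)
    initial_c: float = 0.0
    initial_n: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.plant_c.shape

    @property
    def n_slots(self) -> int:
        return self.biomass.shape[0]

    def site(self, i: int, j: int) -> "Microsite":
        return Microsite(self, i, j)

    # --- derived whole-grid quantities -----------------------------------

    def biomass_by_group(self) -> np.ndarray:
        """Total live biomass C per functional group."""
        out = np.zeros(len(self.groups))
        site_b = self.biomass.sum(axis=0)
        for g in range(len(self.groups)):
            out[g] = site_b[self.group == g].sum()
        return out

    def biomass_n_total(self) -> float:
        """Total live biomass N (cell C:N is fixed per group)."""
        site_b = self.biomass.sum(axis=0)
        total = 0.0
        for g, grp in enumerate(self.groups):
            total += site_b[self.group == g].sum() / grp.cell_cn
        return total

    def copy(self) -> "SimState":
        rng = np.random.default_rng()
        rng.bit_generator.state = self.rng.bit_generator.state
        return SimState(
            plant_c=self.plant_c.copy(), plant_n=self.plant_n.copy(),
            mrc_c=self.mrc_c.copy(), mrc_n=self.mrc_n.copy(),
            mrn_c=self.mrn_c.copy(), mrn_n=self.mrn_n.copy(),
            dom_c=self.dom_c.copy(), dom_n=self.dom_n.copy(),
            din=self.din.copy(), enzymes=self.enzymes.copy(),
            group=self.group.copy(), biomass=self.biomass.copy(),
            groups=self.groups, rng=rng,
            t=self.t, ledgers=self.ledgers.copy(),
            initial_c=self.initial_c, initial_n=self.initial_n,
        )


class Microsite:
    """Read-only view of one lattice site, for inspection and tests."""

    def __init__(self, state: SimState, i: int, j: int):
        self._s = state
        self.i = i
        self.j = j

    @property
    def plant(self) -> tuple[float, float]:
        return (self._s.plant_c[self.i, self.j], self._s.plant_n[self.i, self.j])

    @property
    def mrc(self) -> tuple[float, float]:
        return (self._s.mrc_c[self.i, self.j], self._s.mrc_n[self.i, self.j])

    @property
    def mrn(self) -> tuple[float, float]:
        return (self._s.mrn_c[self.i, self.j], self._s.mrn_n[self.i, self.j])

    @property
    def dom(self) -> tuple[float, float]:
        return (self._s.dom_c[self.i, self.j], self._s.dom_n[self.i, self.j])

    @property
    def din_n(self) -> float:
        return self._s.din[self.i, self.j]

    @property
    def enzymes(self) -> np.ndarray:
        return self._s.enzymes[:, self.i, self.j]

    @property
    def group_id(self) -> int:
        return int(self._s.group[self.i, self.j])

    @property
    def cells(self) -> list[float]:
        col = self._s.biomass[:, self.i, self.j]
        return [float(b) for b in col if b > 0]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Microsite({self.i},{self.j}: plant={self.plant}, dom={self.dom}, "
            f"group={self.group_id}, cells={self.cells})"
        )


def total_carbon(state: SimState, include_ledgers: bool = True) -> float:
    """Grid-total C: pools + biomass + enzymes (+ respired and leached C)."""
    pools = (
        state.plant_c.sum() + state.mrc_c.sum() + state.mrn_c.sum()
        + state.dom_c.sum() + state.enzymes.sum() + state.biomass.sum()
    )
    if include_ledgers:
        pools += state.ledgers.respired_c + state.ledgers.leached_c
    return float(pools)


def total_nitrogen_with(state: SimState, enzyme_cn: float,
                        include_ledgers: bool = True) -> float:
    """Grid-total N (+ leached N).  Enzyme N is implied by the fixed enzyme
    C:N; biomass N by each group's fixed cell C:N.  No N is respired."""
    pools = (
        state.plant_n.sum() + state.mrc_n.sum() + state.mrn_n.sum()
        + state.dom_n.sum() + state.din.sum()
        + state.enzymes.sum() / enzyme_cn
        + state.biomass_n_total()
    )
    if include_ledgers:
        pools += state.ledgers.leached_n
    return float(pools)


def check_conservation(state: SimState, params: SimulationParams,
                       rtol: float = 1e-9) -> tuple[float, float]:
    """Relative C and N closure errors against the initial totals.

    Raises :class:`StateCorruptionError` if either exceeds ``rtol``.
    """
    c_now = total_carbon(state)
    n_now = total_nitrogen_with(state, params.enzyme_cn)
    c_err = abs(c_now - state.initial_c) / max(state.initial_c, 1e-300)
    n_err = abs(n_now - state.initial_n) / max(state.initial_n, 1e-300)
    if c_err > rtol or n_err > rtol:
        raise StateCorruptionError(
            f"conservation breach at t={state.t}: C err {c_err:.3e}, "
            f"N err {n_err:.3e} (tolerance {rtol:.1e})"
        )
    return c_err, n_err


def init_litter_grid(
    params: SimulationParams,
    litter_cn: float,
    groups: Sequence[FunctionalGroup],
    seed: int | np.random.Generator = 0,
) -> SimState:
    """Build the initial litter grid at a prescribed litter C:N ratio.

    Every microsite receives the same plant-material pool (``init_plant_c``
    fmol C, N = C / ``litter_cn``), DOM and DIN at their configured initial
    values, and empty necromass and enzyme pools.  Each functional group is
    then seeded on a disjoint, uniformly random ``init_occupancy`` fraction
    of sites with one founder cell of biomass MCS/2 (the post-division size).

    Varying ``litter_cn`` at fixed params changes only the plant N content:
    grids at different litter C:N contain identical total carbon.
    """
    if litter_cn <= 0:
        raise ConfigurationError("litter_cn must be positive")
    if not groups:
        raise ConfigurationError("at least one functional group is required")
    n_groups = len(groups)
    if n_groups * params.init_occupancy > 1.0 + 1e-12:
        raise ConfigurationError(
            f"total requested occupancy {n_groups * params.init_occupancy:.3f} > 1"
        )
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    h = w = params.grid_size
    n_sites = h * w
    full = lambda v: np.full((h, w), float(v))

    state = SimState(
        plant_c=full(params.init_plant_c),
        plant_n=full(params.init_plant_c / litter_cn),
        mrc_c=full(0.0), mrc_n=full(0.0),
        mrn_c=full(0.0), mrn_n=full(0.0),
        dom_c=full(params.init_dom_c),
        dom_n=full(params.init_dom_c / params.init_dom_cn),
        din=full(params.init_din),
        enzymes=np.full((3, h, w), params.init_enzyme_c / 3.0),
        group=np.full((h, w), -1, dtype=np.int64),
        biomass=np.zeros((max(g.max_cells_per_site for g in groups), h, w)),
        groups=tuple(groups),
        rng=rng,
    )

    per_group = int(round(params.init_occupancy * n_sites))
    order = rng.permutation(n_sites)
    flat_group = state.group.reshape(-1)
    flat_b0 = state.biomass[0].reshape(-1)
    for g, grp in enumerate(groups):
        chosen = order[g * per_group : (g + 1) * per_group]
        flat_group[chosen] = g
        flat_b0[chosen] = grp.mcs / 2.0

    state.initial_c = total_carbon(state)
    state.initial_n = total_nitrogen_with(state, enzyme_cn=params.enzyme_cn)
    return state
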