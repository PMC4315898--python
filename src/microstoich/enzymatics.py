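"""Extracellular enzymatic degradation and enzyme turnover.

Each of the three complex substrate pools (plant material, C-rich microbial
remains, N-rich microbial remains) is degraded by its own enzyme class
following Michaelis-Menten kinetics; the products enter the DOM pool of the
same microsite at the source pool's C:N ratio.  Active enzymes denature at a
constant per-step rate (exponential lifetime) into the N-rich necromass pool.

All operations act on the whole grid at once; the per-site update is
independent of every other site, so the vectorised form is exact.
"""

from __future__ import annotations

import numpy as np

from .core_model import SimState, SimulationParams, StateCorruptionError

__all__ = ["degrade_pools", "age_enzymes"]


def degrade_pools(
    state: SimState, params: SimulationParams
) -> tuple[np.ndarray, np.ndarray]:
    """One step of enzymatic breakdown at every microsite (in place).

    For enzyme class *i* with pool ``E_i`` acting on substrate ``S_i``::

        flux_C_i = vmax_i * E_i * S_i / (km_i + S_i)   (capped at S_i)

    The accompanying N flux preserves the source pool's C:N.  Returns
    ``(flux_c, flux_n)`` with shape ``(3, H, W)``.
    """
    pools_c = (state.plant_c, state.mrc_c, state.mrn_c)
    pools_n = (state.plant_n, state.mrc_n, state.mrn_n)
    flux_c = np.zeros_like(state.enzymes)
    flux_n = np.zeros_like(state.enzymes)
    for i in range(3):
        s_c, s_n = pools_c[i], pools_n[i]
        if np.any(s_c < 0) or np.any(s_n < 0):
            raise StateCorruptionError(f"negative substrate pool (class {i})")
        e = state.enzymes[i]
        denom = params.km[i] + s_c
        fc = np.where(denom > 0, params.vmax[i] * e * s_c / np.where(denom > 0, denom, 1.0), 0.0)
        np.minimum(fc, s_c, out=fc)
        # products inherit the source stoichiometry; remove N proportionally
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(s_c > 0, fc / np.where(s_c > 0, s_c, 1.0), 0.0)
        fn = ratio * s_n
        s_c -= fc
        s_n -= fn
        flux_c[i] = fc
        flux_n[i] = fn
    state.dom_c += flux_c.sum(axis=0)
    state.dom_n += flux_n.sum(axis=0)
    return flux_c, flux_n


def age_enzymes(state: SimState, params: SimulationParams) -> np.ndarray:
    """Shift denatured enzymes into the N-rich microbial-remains pool.

    A fraction ``1/enzyme_lifetime`` of every enzyme pool denatures per step
    (memoryless decay with the configured mean lifetime).  The C moves to
    MR-N together with its N at the fixed enzyme C:N, so MR-N retains its
    protein-like stoichiometry.  Returns the per-class denatured C
    (``(3, H, W)``).
    """
    if not np.isfinite(params.enzyme_lifetime) or params.enzyme_lifetime <= 0:
        return np.zeros_like(state.enzymes)
    frac = min(1.0, 1.0 / params.enzyme_lifetime)
    dead = state.enzymes * frac
    state.enzymes -= dead
    dead_total = dead.sum(axis=0)
    state.mrn_c += dead_total
    state.mrn_n += dead_total / params.enzyme_cn
    return dead
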