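"""Diffusion of dissolved pools between microsites, with leaching losses.

DOM (C and N together) and DIN exchange with the four von-Neumann
neighbours every step: a site sends ``diff * amount / 4`` to each neighbour
(synchronous discrete Laplacian; the simulation lattice is toroidal).  A
configurable fraction of every parcel in transit is lost by leaching and
booked to the run's leached-C/-N ledgers; the rest arrives.
"""

from __future__ import annotations

import numpy as np

from .core_model import ConfigurationError, SimState, SimulationParams

__all__ = ["diffuse_and_leach", "diffuse_field"]


def diffuse_field(
    field: np.ndarray,
    diff: float,
    leach_fract: float,
    toroidal: bool = True,
) -> tuple[np.ndarray, float]:
    """One synchronous diffusion step on a 2-D lattice.

    Every site sends ``diff * amount / 4`` to each of its von-Neumann
    neighbours; with ``toroidal=False`` boundaries are closed (edge sites
    simply have fewer neighbours).  Returns the new field and the total
    amount removed by leaching.
    """
    if not 0.0 <= diff <= 1.0:
        raise ConfigurationError(f"diffusion fraction must lie in [0, 1]: {diff}")
    per_neighbour = diff * field / 4.0
    arriving = np.zeros_like(field)
    sent = np.zeros_like(field)
    for axis in (0, 1):
        if field.shape[axis] < 2:
            continue
        if toroidal:
            for shift in (1, -1):
                arriving += np.roll(per_neighbour, shift, axis=axis)
                sent += per_neighbour
        else:
            lead = [slice(None)] * 2
            lag = [slice(None)] * 2
            lead[axis] = slice(1, None)
            lag[axis] = slice(None, -1)
            lead_t, lag_t = tuple(lead), tuple(lag)
            arriving[lead_t] += per_neighbour[lag_t]
            arriving[lag_t] += per_neighbour[lead_t]
            sent[lead_t] += per_neighbour[lead_t]
            sent[lag_t] += per_neighbour[lag_t]
    leached = leach_fract * sent.sum()
    new = field - sent + (1.0 - leach_fract) * arriving
    return new, float(leached)


def diffuse_and_leach(
    state: SimState, params: SimulationParams
) -> tuple[float, float]:
    """Diffuse DOM-C, DOM-N and DIN across the grid (in place).

    Returns ``(leached_c, leached_n)`` for this step and adds them to the
    cumulative ledgers.  DOM carbon and nitrogen diffuse with the same
    coefficient, so transport does not fractionate DOM stoichiometry; DIN
    has its own (typically faster) coefficient and contributes N only.
    """
    state.dom_c, lc = diffuse_field(state.dom_c, params.diff_dom, params.leach_fract)
    state.dom_n, ln_dom = diffuse_field(state.dom_n, params.diff_dom, params.leach_fract)
    state.din, ln_din = diffuse_field(state.din, params.diff_din, params.leach_fract)
    leached_n = ln_dom + ln_din
    state.ledgers.leached_c += lc
    state.ledgers.leached_n += leached_n
    return lc, leached_n
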