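"""Continuous-time rate laws of the vial model.

Three sectors: gas-liquid O₂ kinetics, two-subpopulation growth with an
O₂-gated stochastic recruitment term, and N-oxyanion reduction to N₂.
The public functions operate on scalars; :func:`rhs` assembles the full
right-hand side for a :class:`~denitvial.params.VialState`.
"""

from __future__ import annotations

import math

import numpy as np

from .params import Params, VialState

__all__ = [
    "partial_pressure",
    "o2_transport_rate",
    "v_O2",
    "v_NOx",
    "recruitment_probability",
    "rhs",
    "rhs_array",
]


def partial_pressure(O2_hs: float, params: Params) -> float:
    """Headspace O₂ partial pressure (atm) from the amount (mol vial⁻¹).

    Ideal-gas closure: ``P = n R T / V_hs``.
    """
    if O2_hs < 0:
        raise ValueError(f"headspace O2 amount must be non-negative, got {O2_hs!r}")
    return O2_hs * params.R_gas * params.T / params.V_hs


def o2_transport_rate(P_hs: float, O2_liq_conc: float, params: Params) -> float:
    """Net headspace→liquid O₂ transport rate, mol vial⁻¹ h⁻¹.

    ``kt * (S_O2 * P_hs - c_liq)``: positive when the liquid is
    undersaturated, negative (degassing) when supersaturated, zero at the
    Henry equilibrium ``c_liq = S_O2 * P_hs``.
    """
    return params.kt * (params.S_O2 * P_hs - O2_liq_conc)


def v_O2(O2_liq_conc: float, params: Params) -> float:
    """Cell-specific O₂ consumption velocity (mol cell⁻¹ h⁻¹).

    Michaelis-Menten in the liquid O₂ concentration; negative
    concentrations (solver noise) are clamped to zero.
    """
    c = max(O2_liq_conc, 0.0)
    return params.vmax_O2 * c / (params.Km_O2 + c)


def v_NOx(NOx_conc: float, params: Params) -> float:
    """Cell-specific N-oxyanion reduction velocity (molN cell⁻¹ h⁻¹)."""
    c = max(NOx_conc, 0.0)
    return params.vmax_NOx * c / (params.Km_NOx + c)


def recruitment_probability(O2_liq_conc: float, params: Params) -> float:
    """Specific probability (h⁻¹) of recruitment to denitrification.

    Piecewise constant: equals ``r`` while ``O2_min < c < O2_crit``
    (strict inequalities — the thresholds themselves carry zero hazard),
    zero otherwise.  Above ``O2_crit`` *nirS* transcription is suppressed
    by O₂; below ``O2_min`` the cells lack aerobic energy for enzyme
    synthesis.
    """
    if params.O2_min < O2_liq_conc < params.O2_crit:
        return params.r
    return 0.0


def rhs_array(t: float, y, p: Params) -> list:
    """ODE right-hand side on the raw state vector (solver form).

    State order follows :data:`~denitvial.params.STATE_FIELDS`.  Written
    with plain floats: this function dominates the simulation cost.
    """
    O2_hs = y[0]
    c = y[1] / p.V_liq
    if c < 0.0:
        c = 0.0
    N_p = y[2]
    N_d = y[3]
    cn = y[4] / p.V_liq
    if cn < 0.0:
        cn = 0.0

    P_hs = (O2_hs if O2_hs > 0.0 else 0.0) * p.R_gas * p.T / p.V_hs
    transport = p.kt * (p.S_O2 * P_hs - c)
    vo = p.vmax_O2 * c / (p.Km_O2 + c)
    vn = p.vmax_NOx * cn / (p.Km_NOx + cn)
    haz = p.r if (p.O2_min < c < p.O2_crit) else 0.0

    consumption = (N_p + N_d) * vo
    reduction = N_d * vn

    d = [
        -transport,
        transport - consumption,
        vo * p.Y_O2 * N_p - haz * N_p,
        haz * N_p + vn * p.Y_NOx * N_d + vo * p.Y_O2 * N_d,
        -reduction,
        reduction,
        consumption,
        reduction,
        haz,
    ]
    # single cheap guard: any nan/inf in states or fluxes poisons the sum
    total = y[0] + y[4] + transport + consumption + reduction + N_p + N_d
    if not math.isfinite(total):
        raise FloatingPointError(f"non-finite derivative at t={t!r}: state is invalid")
    return d


def rhs(state: VialState, params: Params) -> VialState:
    """Time derivative of every state entry, as a :class:`VialState` record."""
    return VialState.from_array(np.asarray(rhs_array(0.0, state.to_array(), params)))
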