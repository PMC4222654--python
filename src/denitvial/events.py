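"""Discrete modifications of the continuous vial state.

Two kinds of events interrupt the ODE flow: robotised headspace sampling
(He dilution plus a small O₂ leak through the injection system) and the
sparging event of the diauxic-lag variant.  Both are applied as
instantaneous jumps: the sampling duration (0.017 h) is far below every
system time constant, so the integrated effect of a jump is identical to a
rate spread over the sampling interval.
"""

from __future__ import annotations

import dataclasses

from .params import Params, SpargeEvent, VialState

__all__ = ["apply_sampling", "apply_sparge", "sampling_fixed_point"]


def apply_sampling(state: VialState, params: Params) -> VialState:
    """One headspace sampling: He dilution plus O₂ leakage.

    Only the headspace O₂ amount changes::

        O2_hs <- O2_hs * (1 - dil) + O2_leak

    The N₂ and N-oxyanion pools are deliberately untouched: measured N₂ in
    the emulated system is reported cumulatively, already corrected for the
    net sampling effect, so the model ignores sampling losses of N₂.  The
    net change is negative iff ``O2_hs > O2_leak / dil`` (≈ 0.583 µmol);
    below that the leak dominates and sampling *adds* O₂.
    """
    new_hs = state.O2_hs * (1.0 - params.dil) + params.O2_leak
    return dataclasses.replace(state, O2_hs=new_hs)


def sampling_fixed_point(params: Params) -> float:
    """Headspace O₂ amount at which a sampling event is neutral (mol)."""
    return params.O2_leak / params.dil


def apply_sparge(state: VialState, sparge: SpargeEvent, params: Params) -> VialState:
    """Sparging: headspace O₂ drops instantly to ``floor_hs``.

    With ``also_liquid`` the liquid is forced to the Henry equilibrium
    implied by the floor; otherwise it is left to be consumed or degassed
    by the continuous dynamics.  Idempotent: applying twice equals once.
    """
    from .rates import partial_pressure

    changes: dict[str, float] = {"O2_hs": sparge.floor_hs}
    if sparge.also_liquid:
        p_hs = partial_pressure(sparge.floor_hs, params)
        changes["O2_liq"] = params.S_O2 * p_hs * params.V_liq
    return dataclasses.replace(state, **changes)
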