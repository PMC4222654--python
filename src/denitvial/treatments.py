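"""Reference treatment definitions.

The nine reference batch treatments cross three nominal headspace O₂
levels (~0, 1 and 7 vol.%) with three nitrite concentrations (0.2, 1 and
2 mM in 50 mL of medium).  The actual initial headspace O₂ amounts differ
slightly between vials of the same nominal level because He-washing leaves
variable traces of O₂ behind; the amounts below are the per-vial values
used in the simulations.
"""

from __future__ import annotations

from .params import DEFAULT_PARAMS, Params, Treatment

__all__ = [
    "BATCH_CONDITIONS",
    "batch_treatment",
    "all_batch_treatments",
    "SENSITIVITY_HIGH_O2",
    "SENSITIVITY_LOW_O2",
    "sensitivity_treatment",
]

#: Batch number -> (initial headspace O2, mol vial^-1; nitrite, mM).
BATCH_CONDITIONS: dict[int, tuple[float, float]] = {
    1: (2.0e-6, 0.2),
    2: (1.5e-6, 1.0),
    3: (1.7e-6, 2.0),
    4: (50.1e-6, 0.2),
    5: (37.8e-6, 1.0),
    6: (38.4e-6, 2.0),
    7: (199e-6, 0.2),
    8: (200e-6, 1.0),
    9: (200e-6, 2.0),
}

#: Initial headspace O2 (mol vial^-1) for the high-range sensitivity runs
#: (far above the recruitment-trigger concentration), runs 1..3.
SENSITIVITY_HIGH_O2: tuple[float, ...] = (2.0e-4, 1.19e-4, 3.84e-5)

#: Initial headspace O2 (mol vial^-1) for the low-range sensitivity runs
#: (liquid equilibrium marginally below the trigger concentration downward).
SENSITIVITY_LOW_O2: tuple[float, ...] = (2.02e-5, 1.01e-5, 5.04e-6)


def nitrite_mm_to_moln(mm: float, params: Params = DEFAULT_PARAMS) -> float:
    """Convert a nitrite concentration in mM to molN per vial."""
    return mm * 1e-3 * params.V_liq


def batch_treatment(
    batch: int, params: Params = DEFAULT_PARAMS, horizon: float = 150.0
) -> Treatment:
    """Treatment definition for one of the nine reference batches."""
    try:
        o2_hs_0, nox_mm = BATCH_CONDITIONS[batch]
    except KeyError:
        raise ValueError(f"batch must be 1..9, got {batch!r}") from None
    return Treatment(
        O2_hs_0=o2_hs_0,
        NOx_0=nitrite_mm_to_moln(nox_mm, params),
        horizon=horizon,
    )


def all_batch_treatments(
    params: Params = DEFAULT_PARAMS, horizon: float = 150.0
) -> dict[int, Treatment]:
    return {b: batch_treatment(b, params, horizon) for b in BATCH_CONDITIONS}


def sensitivity_treatment(
    o2_hs_0: float,
    nox_mm: float = 1.0,
    params: Params = DEFAULT_PARAMS,
    horizon: float = 150.0,
) -> Treatment:
    """Sensitivity-run treatment: given initial O₂, defaults otherwise.

    The nitrite pool defaults to 1 mM; any value far above the
    half-saturation constant is equivalent for the recruited fraction.
    """
    return Treatment(
        O2_hs_0=o2_hs_0,
        NOx_0=nitrite_mm_to_moln(nox_mm, params),
        horizon=horizon,
    )
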