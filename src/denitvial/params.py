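"""Domain types: model parameters, vial state, treatments and schedules.

All amounts are stored *per vial* (mol vial⁻¹ for gases and N-oxyanions,
cells vial⁻¹ for the two subpopulations).  Concentrations are always derived
by dividing by the liquid volume ``V_liq``; there is no duplicate
concentration bookkeeping anywhere in the model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Params",
    "VialState",
    "SamplingSchedule",
    "SpargeEvent",
    "Treatment",
    "DEFAULT_PARAMS",
    "STATE_FIELDS",
]


@dataclass(frozen=True)
class Params:
    """Rate, transfer and yield constants of the vial model.

    The defaults are the reference parameter set for batch incubations of
    *Paracoccus denitrificans* in 120-mL vials (70 mL headspace, 50 mL
    medium) at 20 °C, monitored by a robotised headspace-sampling GC system.

    Attributes
    ----------
    dil : float
        Fraction of headspace gas replaced by He during one sampling
        (dimensionless).
    S_O2 : float
        O₂ solubility in water at 20 °C, mol L⁻¹ atm⁻¹.
    kt : float
        Headspace↔liquid O₂ transport coefficient, L vial⁻¹ h⁻¹.
    O2_leak : float
        O₂ leaked into the vial through the injection system per sampling,
        mol vial⁻¹.
    t_samp : float
        Duration of one sampling, h.
    Km_O2 : float
        Half-saturation constant for O₂ consumption, mol L⁻¹.
    vmax_O2 : float
        Maximum cell-specific O₂ consumption velocity, mol cell⁻¹ h⁻¹.
    O2_min : float
        Liquid [O₂] below which recruitment to denitrification halts for
        lack of aerobic energy, mol L⁻¹.
    O2_crit : float
        Liquid [O₂] below which *nirS* transcription is de-repressed and
        recruitment can trigger, mol L⁻¹.
    r : float
        Specific probability of recruitment of a cell to denitrification
        while O2_min < [O₂] < O2_crit, h⁻¹.
    Y_NOx : float
        Growth yield per molN of N-oxyanion respired, cells molN⁻¹.
    Y_O2 : float
        Growth yield per mol O₂ respired, cells mol⁻¹.
    Km_NOx : float
        Half-saturation constant for N-oxyanion reduction, molN L⁻¹.
    vmax_NOx : float
        Maximum cell-specific N-oxyanion reduction velocity,
        molN cell⁻¹ h⁻¹.
    R_gas : float
        Universal gas constant, L atm K⁻¹ mol⁻¹.
    T : float
        Incubation temperature, K.
    V_hs : float
        Headspace volume, L vial⁻¹.
    V_liq : float
        Liquid-phase volume, L vial⁻¹.
    """

    dil: float = 0.035
    S_O2: float = 0.00139
    kt: float = 1.62
    O2_leak: float = 2.04e-8
    t_samp: float = 0.017
    Km_O2: float = 2.5e-7
    vmax_O2: float = 1.33e-15
    O2_min: float = 1e-9
    O2_crit: float = 9.75e-6
    r: float = 0.0052
    Y_NOx: float = 5.79e13
    Y_O2: float = 15e13
    Km_NOx: float = 4e-6
    vmax_NOx: float = 1.83e-15
    R_gas: float = 0.083
    T: float = 293.1
    V_hs: float = 0.07
    V_liq: float = 0.05

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                if name == "r" and value == 0.0:
                    continue  # r = 0 is a legitimate no-recruitment scenario
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value!r}")
        if not 0 < self.dil < 1:
            raise ValueError(f"dil must lie in (0, 1), got {self.dil!r}")
        if not self.O2_min < self.O2_crit:
            raise ValueError(
                f"O2_min ({self.O2_min!r}) must be below O2_crit ({self.O2_crit!r})"
            )

    def evolve(self, **overrides: float) -> "Params":
        """Return a copy with the given fields replaced.

        Unknown field names raise ``TypeError``; the new instance is
        re-validated.
        """
        return dataclasses.replace(self, **overrides)


DEFAULT_PARAMS = Params()

#: Canonical ordering of the ODE state vector.
STATE_FIELDS = (
    "O2_hs",
    "O2_liq",
    "N_p",
    "N_d",
    "NOx",
    "N2",
    "cum_O2_consumed",
    "cum_NOx_consumed",
    "cum_r_dt",
)


@dataclass(frozen=True)
class VialState:
    """Instantaneous amounts in one vial plus auxiliary integrals.

    ``cum_O2_consumed``, ``cum_NOx_consumed`` and ``cum_r_dt`` are carried
    as extra ODE states so that mass-balance audits and the recruited
    fraction are solver-accurate rather than post-hoc quadrature.
    """

    O2_hs: float  # headspace O2, mol vial^-1
    O2_liq: float  # liquid O2, mol vial^-1
    N_p: float  # cells without denitrification proteome, cells vial^-1
    N_d: float  # cells with denitrification proteome, cells vial^-1
    NOx: float  # N-oxyanion pool, molN vial^-1
    N2: float = 0.0  # cumulative N2 produced, molN vial^-1
    cum_O2_consumed: float = 0.0  # mol vial^-1
    cum_NOx_consumed: float = 0.0  # molN vial^-1
    cum_r_dt: float = 0.0  # dimensionless hazard integral

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "VialState":
        return cls(*(float(v) for v in y))

    def o2_liq_conc(self, params: Params) -> float:
        """Liquid [O₂] in mol L⁻¹."""
        return self.O2_liq / params.V_liq

    def nox_conc(self, params: Params) -> float:
        """Liquid N-oxyanion concentration in molN L⁻¹."""
        return self.NOx / params.V_liq


@dataclass(frozen=True)
class SamplingSchedule:
    """Regular headspace-sampling clock.

    The robotised incubation system samples the headspace every
    ``interval`` hours starting at ``first_time``.  Whether the
    experimental clock started at inoculation or at the first measurement
    is not known; ``first_time`` makes the offset explicit.
    """

    interval: float = 3.0
    first_time: float = 3.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("sampling interval must be positive")
        if self.first_time < 0:
            raise ValueError("first sampling time must be non-negative")

    def times(self, horizon: float) -> np.ndarray:
        """Sampling times in ``(0, horizon]``."""
        if not self.enabled or self.first_time > horizon:
            return np.empty(0)
        n = int(np.floor((horizon - self.first_time) / self.interval)) + 1
        return self.first_time + self.interval * np.arange(n)


@dataclass(frozen=True)
class SpargeEvent:
    """Instantaneous removal of headspace O₂ by N₂/He sparging.

    ``floor_hs`` is the residual headspace O₂ amount after sparging.  By
    default the liquid phase is left untouched (it is consumed or degassed
    within minutes); set ``also_liquid`` to force the liquid to the
    equilibrium value implied by ``floor_hs``.
    """

    time: float
    floor_hs: float = 1e-9
    also_liquid: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("sparge time must be non-negative")
        if self.floor_hs < 0:
            raise ValueError("sparge floor must be non-negative")


@dataclass(frozen=True)
class Treatment:
    """Initial amounts, schedule and horizon for one vial.

    ``NOx_0`` is the initial N-oxyanion pool in molN vial⁻¹ (a nitrite
    concentration of c mM in 50 mL corresponds to ``c * 5e-5`` molN).
    """

    O2_hs_0: float  # mol vial^-1
    NOx_0: float  # molN vial^-1
    N_p_0: float = 3e8  # cells vial^-1
    schedule: SamplingSchedule = field(default_factory=SamplingSchedule)
    horizon: float = 150.0  # h
    oxyanion_kind: str = "nitrite"
    sparge: SpargeEvent | None = None

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        for name in ("O2_hs_0", "NOx_0", "N_p_0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.oxyanion_kind not in ("nitrite", "nitrate"):
            raise ValueError("oxyanion_kind must be 'nitrite' or 'nitrate'")

    def initial_state(self, params: Params) -> VialState:
        """Initial vial state with the liquid at gas-liquid equilibrium."""
        from .rates import partial_pressure  # local import avoids a cycle

        p_hs = partial_pressure(self.O2_hs_0, params)
        o2_liq = params.S_O2 * p_hs * params.V_liq
        return VialState(
            O2_hs=self.O2_hs_0,
            O2_liq=o2_liq,
            N_p=self.N_p_0,
            N_d=0.0,
            NOx=self.NOx_0,
        )
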