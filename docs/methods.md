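# Methods

## The model

`denitvial` simulates a sealed batch vial (70 mL headspace, 50 mL medium,
20 °C) in which a non-fermentative denitrifier (*Paracoccus denitrificans*)
consumes an initial dose of O₂ and then switches — partially — to
denitrification of nitrite (or nitrate, in the sparged variant). The state
of one vial is nine ODE components, all stored per vial:

* `O2_hs`, `O2_liq` — headspace and dissolved O₂ (mol). The headspace
  exchanges with the liquid at rate `kt·(S_O2·P − c)`, with the partial
  pressure `P = n·R·T/V_hs` from the ideal-gas law and `c` the dissolved
  concentration.
* `N_p`, `N_d` — cells without and with denitrification proteome
  (cells). Both respire O₂ with Michaelis–Menten cell-specific velocity
  `v_O2 = vmax_O2·c/(Km_O2+c)` and grow with yield `Y_O2`; `N_d`
  additionally reduces the N-oxyanion pool with velocity
  `v_NOx = vmax_NOx·c_N/(Km_NOx+c_N)` and yield `Y_NOx`.
* `NOx`, `N2` — the N-oxyanion pool and cumulative N₂ (molN). Every molN
  reduced appears as N₂; the intermediates NO and N₂O are not modelled
  (they accumulate to negligible amounts under these conditions).
* three auxiliary integrals: cumulative O₂ consumed, cumulative NOx
  consumed, and the recruitment-hazard integral `∫r dt`.

**Recruitment.** A cell without denitrification proteome initiates *nirS*
transcription — and is thereby irreversibly recruited to the denitrifying
pool — with a constant specific probability `r` (h⁻¹) while the dissolved
O₂ concentration lies strictly between two thresholds: above `O2_crit`
(9.75 µM) transcription is repressed by O₂; below `O2_min` (1 nM) the cell
lacks aerobic energy for enzyme synthesis. The recruited fraction over a
simulation is the survival complement of the accumulated hazard,

    F_den = 1 − exp(−∫ r dt),

with the integral carried as an ODE state so it is solver-accurate rather
than post-hoc quadrature. Because the hazard is piecewise constant, for a
single contiguous window (t₁, t₂) this reduces to `1 − exp(−r·(t₂−t₁))`.

**Sampling events.** The emulated robotised incubation system samples the
headspace every 3 h (first sample at t = 3 h by default; the experimental
clock offset is not documented and is exposed as `first_time`). Each
sampling replaces a fraction `dil = 3.5 %` of the headspace with He and
leaks `O2_leak = 2.04e-8` mol of O₂ into the vial; the jump is applied
instantaneously because the sampling duration (0.017 h) is far below every
system time constant. The net change is zero at `O2_leak/dil = 0.583 µmol`
of headspace O₂. N₂ bookkeeping deliberately ignores sampling: the
instrument reports cumulative N₂ already corrected for sampling losses.

## Parameters

Defaults (see `Params`) are the reference constants for this system:
gas-transfer `kt = 1.62 L h⁻¹`, solubility `S_O2 = 1.39e-3 mol L⁻¹ atm⁻¹`,
`vmax_O2 = 1.33e-15 mol cell⁻¹ h⁻¹`, `Km_O2 = 2.5e-7 M`,
`Y_O2 = 1.5e14 cells mol⁻¹`, `vmax_NOx = 1.83e-15 molN cell⁻¹ h⁻¹`,
`Km_NOx = 4e-6 M`, `Y_NOx = 5.79e13 cells molN⁻¹`, recruitment window
(1 nM, 9.75 µM) and `r = 0.0052 h⁻¹`. `O2_min` is an assumption (it would
sustain ~0.4 % of the maximal respiration rate); its influence on the
calibrated `r` is quantified by `sensitivity_O2_min`. The nine reference
treatments cross initial headspace O₂ of ~0, 1 and 7 vol.% (2–200 µmol,
per-vial values as measured after He-washing) with 0.2/1/2 mM nitrite, all
inoculated with 3e8 cells.

## Numerics

Integration uses LSODA (stiff-capable; the cell pools and the µmol-scale
gas pools span ~10 orders of magnitude) with `rtol = 1e-8` and per-state
absolute tolerances set to 1e-12 of each state's characteristic magnitude.
The integration restarts at every sampling event, sparge event and
threshold crossing, so the solver never steps across a discontinuity of
the right-hand side; crossings are localised by the solver's root-finder.
After a crossing the state is nudged by a 1e-7 h Euler microstep so the
event function re-arms with a definite sign; `max_step = 0.25 h` guarantees
that brief leak-driven O₂ excursions between samplings cannot be stepped
over. Concentrations are clamped at zero inside the rate laws; threshold
comparisons are strict (equality carries zero hazard — a measure-zero
choice that cannot affect any integral). A run stops early once the
N-oxyanion pool is exhausted (< 1e-12 molN) and the dissolved O₂ is below
`O2_min`: past that point nothing but the perpetual sampling leak cycle
changes, and letting it run would accumulate physically meaningless
post-exhaustion hazard. The default horizon is 150 h.

**Window reporting.** `t1` (first downward crossing of `O2_crit`, 0 if the
run starts below it), `t2` (first downward crossing of `O2_min` after
`t1`) and `t2_last` (the final one) are exposed per trajectory. In the
~0 vol.% treatments the sampling leak repeatedly lifts the dissolved O₂
back above `O2_min` after initial depletion ("recruitment spikes"), and
between samplings the concentration bottoms within a factor ~2 of the
1 nM threshold — so how the active time splits into "initial window" and
"spikes" is numerically delicate. The reported window length is therefore
`recruitment_span = ∫r dt / r`, the total hazard-active time: identical to
`t2 − t1` for spike-free runs (to < 0.1 %) and robust to the marginal dips
otherwise. This is the package's own design choice for a quantity the
window-splitting conventions leave ambiguous.

## Calibration

`fit_r` minimises the unweighted SSE between simulated and observed
cumulative N₂ at the observation times, by bounded scalar search over
`r ∈ [1e-4, 1] h⁻¹` (`xatol = 1e-5`). N₂ is the fitted observable because
it integrates the recruitment history; observations before the window
carry essentially no information on `r` and are retained (they contribute
~0 to the SSE). The objective is unimodal over the default bounds on
synthetic data (verified by grid scan). Boundary solutions and
non-convergence are flagged, never silently accepted. Joint
multi-parameter estimation and uncertainty intervals on `r` are out of
scope.

## Synthetic data

`generate_measured_table` emulates the instrument output: observations of
headspace O₂ and cumulative N₂ at the sampling times, taken from the
*post-sampling* state (what the gas chromatograph sees), with independent
multiplicative lognormal noise (default CV 2 %, chosen to mimic GC
precision; relative noise suits amounts spanning decades) and a 1e-9 mol
detection floor. What it does *not* emulate: needle clogging, variable
leak episodes, nitrite inhibition of aerobic respiration (visible in real
2 mM nitrite treatments), or O₂-measurement error structure beyond the
lognormal CV. Passing recovery tests therefore demonstrate identifiability
of `r` under the idealised noise model, not robustness to instrument
pathologies.

## Sparged-culture ("diauxic lag") variant

`DiauxicConfig` re-parameterises the model for oxic nitrate-grown cultures
sparged with N₂: sampling disabled, `vmax_O2 = 2.28e-15` (matching the
reported maximal aerobic growth rate 0.342 h⁻¹), nitrate yield
`9.65e13 cells molN⁻¹` and `vmax_NO3 = 2e-15 molN cell⁻¹ h⁻¹`, inoculum
6.5e9 cells (OD₅₅₀ = 0.07; OD is converted linearly with that anchor).
Note an internal inconsistency of the printed source values: `vmax_NO3 ×
Y_NO3` implies an anaerobic growth rate of 0.193 h⁻¹, not the reported
0.322 h⁻¹; the printed values are used as-is. The pre-sparge headspace
defaults to an air-equivalent 6.2e-4 mol so growth is unrestricted before
sparging; the residual O₂ after sparging was never measured in the
original experiment, so this variant is qualitative by construction: tests
assert directions (later sparge → higher density → smaller recruited
fraction → longer apparent lag; log-linear growth of the recruited pool),
not the illustrative printed fractions. With the defaults, the dissolved
O₂ left in the liquid re-partitions into the sparged headspace and
sustains a recruitment window of a few hours, giving recruited fractions
of a few percent.

`detect_lag` operationalises "a period of little or no growth" as the time
after sparging until total OD exceeds its sparge-time value by 5 %
(configurable); for pure exponential growth at rate µ this returns
`ln(1.05)/µ`.

## Problem sizes and runtimes

A 150 h batch simulation takes a few tenths of a second; the full
nine-batch table runs in ~3 s. The parameter-recovery experiment defaults
to 20 synthetic vials on the 50.1 µmol / 0.2 mM conditions with a 60 h
horizon (~20 observations each), which completes in under two minutes.

## Known limitations

* The two-subpopulation split is binary; within-population heterogeneity
  in respiration rates is not represented.
* Nitrite inhibition of aerobic respiration is not modelled, so measured
  O₂ curves of high-nitrite treatments are not reproduced.
* NO/N₂O pools, CO₂, and the underlying transcription network (FnrP/NNR)
  are outside the model boundary; the recruitment gate is their lumped
  surrogate.
* The recruitment hazard is constant within the window; any dependence of
  the switching probability on the O₂ level inside the window is not
  represented.
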