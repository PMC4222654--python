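# denitvial

Dynamic vial model of bacterial recruitment to denitrification:
simulation, calibration and synthetic gas kinetics.

## The problem

Denitrifying bacteria such as *Paracoccus denitrificans* are
non-fermentative: when O₂ runs out they can only keep respiring by
reducing nitrogen oxyanions (NO₂⁻/NO₃⁻ → N₂), and synthesising that
denitrification proteome itself requires energy from aerobic respiration.
A cell that has not made a minimum of denitrification enzymes before O₂
is exhausted is *entrapped in anoxia*. Gas kinetics from sealed batch
vials suggest that only a small fraction of a population manages the
switch — a bet-hedging outcome.

`denitvial` models one vial as a stiff ODE system with discrete events:
headspace↔liquid O₂ transfer, Michaelis–Menten respiration and growth of
two subpopulations (N_p without and N_d with denitrification proteome),
NO₂⁻ → N₂ kinetics, and 3-hourly headspace-sampling events that dilute the
headspace with He while leaking a trace of O₂ back in. Recruitment of
cells from N_p to N_d is a constant hazard r (h⁻¹) that is active only
while the dissolved O₂ concentration lies between two thresholds
(O2_min = 1 nM < [O₂] < O2_crit = 9.75 µM). The recruited fraction is

    F_den = 1 − exp(−∫ r dt),

the survival complement of the accumulated hazard over the recruitment
window. The package simulates treatments, computes F_den and the window
boundaries, calibrates r against measured (or synthetic) cumulative-N₂
tables, generates synthetic instrument output for testing, and includes a
sparged-culture variant showing how a minute recruited fraction produces
an apparent "diauxic" growth lag. See `docs/methods.md` for the full
model description.

## Worked example

Simulate the nine reference batch treatments (three initial O₂ levels
crossed with three nitrite concentrations) and tabulate the recruitment
window and recruited fraction:

```sh
denitvial reproduce-tables --out out/
```

```
batch  O2_hs_0_umol  NOx_mM  recruitment_span_h  F_den
    1           2.0     0.2               28.20 0.1364
    2           1.5     1.0               30.92 0.1485
    3           1.7     2.0               30.00 0.1444
    4          50.1     0.2               10.12 0.0513
    5          37.8     1.0               11.76 0.0593
    6          38.4     2.0               11.63 0.0587
    7         199.0     0.2                7.41 0.0378
    8         200.0     1.0                7.40 0.0377
    9         200.0     2.0                7.40 0.0377
 mean           NaN     NaN                 NaN 0.0791
```

Reading the table: more initial O₂ means more aerobically grown cells at
the moment of O₂ depletion, hence faster depletion through the
recruitment window — the window shrinks from ~28–31 h (~0 vol.% O₂
batches, where sampling leaks repeatedly re-open it) to 7.4 h (7 vol.%),
and the recruited fraction falls from ~14 % to ~3.8 %. The mean recruited
fraction across the nine treatments is ~8 % — the great majority of every
population stays entrapped in anoxia.

The same from Python, plus calibration on synthetic data:

```python
import dataclasses
from denitvial import (batch_treatment, simulate, generate_measured_table,
                       NoiseModel, fit_r)

traj = simulate(batch_treatment(7))
print(traj.recruitment_span, traj.F_den)   # 7.405 0.0378

trt = dataclasses.replace(batch_treatment(4), horizon=60.0)
table = generate_measured_table(trt, r_true=0.0052,
                                noise=NoiseModel(cv=0.02, seed=1))
print(fit_r(table, trt).r_opt)             # 0.00515
```

Other CLI modes: `simulate` (one vial from a YAML config), `generate`
(synthetic measured table), `calibrate` (fit r to measured tables),
`diauxic` (sparged-culture variant). All accept `--set key=value`
parameter overrides; for example `--set r=1` forces full recruitment,
which grossly overestimates N₂ accumulation — the model's argument
against a homogeneous-population interpretation.

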