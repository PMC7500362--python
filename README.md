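# mimsflux

Data processing for membrane-inlet mass spectrometry (MIMS) in algal and
cyanobacterial gas-exchange research: from raw multi-channel ion-current
traces to calibrated dissolved-gas concentrations, consumption-corrected
biological fluxes, and the standard isotope analyses of photosynthesis
physiology — with a forward simulator so every stage is testable without
an instrument.

In a MIMS setup a gas-permeable membrane at the bottom of a closed,
thermo-regulated reaction vessel admits dissolved gases to a mass
spectrometer.  Each channel current is linear in the concentration of the
contributing gases, and the instrument itself consumes gas through the
membrane at a first-order rate, so the biological exchange rate of gas
*g* is

    v_g(t) = dC_g/dt + k_g · C_g(t)

(positive = release, negative = uptake).  On top of this flux calculus the
package implements:

* **Registry** — fragmentation patterns (base peak = 100) and solubility
  tables for H₂, D₂, H₂O, N₂, NO, O₂, Ar, CO₂, N₂O plus the isotopologues
  ¹⁸O₂ (m/z 36), ¹⁶O¹⁸O (34), HD (3), ¹³CO₂ (45), ¹³C¹⁸O¹⁶O (47),
  ¹³C¹⁸O₂ (49), packaged as a replaceable YAML config.
* **Calibration** — two-point (air + zero) or spiked-standard sensitivity
  and baseline, per-gas consumption constants from abiotic decays, and
  inert-reference normalization that cancels common-mode drift exactly.
* **Unmixing** — nonnegative least squares over the fragmentation matrix
  for overlapped channels (CO₂/N₂O at m/z 44, CO₂ on m/z 28 under N₂,
  D₂'s 1.59 % fragment on the H₂ channel).
* **¹⁸O₂/¹⁶O₂ partitioning** — gross O₂ evolution, gross uptake, net O₂:
  `uptake = v₁₈(1 + C₁₆/C₁₈)`, `evolution = v₁₆ − v₁₈·C₁₆/C₁₈`,
  `net = evolution + uptake` (exact identity).
* **H/D exchange** — hydrogenase activity
  `V_exch = (2·v_H₂ + v_HD)/τ` with the deuterium atom fraction
  `τ = (C_D₂ + C_HD/2)/(C_D₂ + C_H₂ + C_HD)`.
* **CA kinetics** — ¹⁸O content of ¹³CO₂,
  `α = (2C₄₉ + C₄₇)/(C₄₉ + C₄₇ + C₄₅)`, fitted as `α = a₁·e^(−θt)`.
* **Ci affinity** — Michaelis–Menten `K₁/₂` from a single light-driven
  depletion run, and CO₂-vs-HCO₃⁻ uptake partitioning by the
  disequilibrium method (two-species carbonate chemistry).
* **Simulator** — virtual instrument presets for the four canonical
  closed-vessel protocols, emitting noisy traces plus ground truth.

## Worked example

Simulate the ¹⁸O₂-labeling protocol (¹⁸O₂ spike, 5 min dark, 10 min
light) and partition the O₂ exchange:

```python
import numpy as np
from mimsflux import (load_gas_registry, preset, simulate,
                      signal_to_concentration, compute_flux,
                      o2_exchange_rates)
from mimsflux.simulator import truth_calibration

registry = load_gas_registry()
spec = preset("s1_o2_isotope", seed=1, noise_rel=0.01)
trace, truth = simulate(spec, registry)          # 901 samples, m/z 32 + 36

cal = truth_calibration(spec)                    # or fit_two_point_calibration
conc = signal_to_concentration(trace, cal, registry, ["O2", "18O2"])
flux = compute_flux(conc, cal, window=30)        # 30 s sliding average
res = o2_exchange_rates(trace.time, conc["O2"], conc["18O2"],
                        flux["O2"], flux["18O2"])

light = (trace.time > 400) & (trace.time < 800)
print(f"gross evolution {np.nanmean(res.evolution[light]):.3f} umol/L/s")
print(f"gross uptake    {np.nanmean(res.uptake[light]):.3f} umol/L/s")
print(f"net O2          {np.nanmean(res.net[light]):.3f} umol/L/s")
```

Output:

```
gross evolution 0.151 umol/L/s
gross uptake    -0.053 umol/L/s
net O2          0.099 umol/L/s
```

i.e. under illumination the cells gross-produce ~0.15 µmol O₂ L⁻¹ s⁻¹ at
PSII while simultaneously consuming ~0.05 (uptake is negative by
convention), for a net release of ~0.10 — recovering, at 1 % channel
noise, the rates the scenario was generated with (E = 0.150,
U = 0.050 µmol L⁻¹ s⁻¹).

The same pipelines are scriptable from the shell:

```sh
mimsflux simulate --preset s1_o2_isotope --seed 1 --out trace.csv --truth truth.csv
mimsflux o2-isotope --trace trace.csv --cal cal.json --out o2.csv
mimsflux --help     # calibrate, fluxes, unmix, hd-exchange, ca-activity,
                    # ci-affinity, hco3-partition, simulate
```

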