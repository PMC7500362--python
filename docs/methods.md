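# Methods

`mimsflux` implements the data-processing calculus of membrane-inlet mass
spectrometry (MIMS) for dissolved-gas exchange in microalgal and
cyanobacterial suspensions: a closed, thermo-regulated reaction vessel is
separated from the spectrometer's vacuum line by a gas-permeable membrane,
and the instrument reports one ion current per m/z channel over time.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic-data tests do and do not demonstrate.

## Signal model and calibration

On its base-peak channel, gas *g* contributes a current linear in its
dissolved concentration,

    S_g(t) = s_g · C_g(t) + b_g ,

with sensitivity `s_g` (A per µmol L⁻¹) and baseline `b_g` (A).  Membrane
permeation makes the leak to the spectrometer linear in concentration, so
the instrument itself consumes each gas at a first-order rate `k_g·C_g`
(`k_g` in s⁻¹, typically ~10⁻³ for a thin PTFE membrane at millilitre
vessel volumes).  Temperature is assumed constant within a run — the
vessel must be thermo-regulated, since permeation is strongly
temperature-dependent.

Calibration is two-point by default: `b_g` from a segment after an inert
flush, `s_g` from a segment equilibrated with air, using the equilibrium
concentration at the run temperature and the gas's atmospheric partial
pressure (Henry behavior, with the 1-atm solubility linearly interpolated
in a per-species temperature table).  Both segments must be quasi-steady
(relative SD < 1 %, configurable).  Gases absent from air (D₂, HD, the
¹³C/¹⁸O CO₂ isotopologues) take a spiked standard of known concentration
instead.  The packaged solubility tables and air mole fractions are
standard reference data for fresh water and are expected to be replaced
for saline media; they are deliberately in the config file, not the code.

Slow common-mode signal drift (membrane and source fluctuations) is
removed by normalizing all channels to an inert reference gas (Ar or N₂):
any multiplicative disturbance shared across channels cancels exactly,
and the operation is idempotent.  Normalization acts on signals, before
concentration conversion.  If the reference gas itself leaks appreciably,
its decay is divided into every channel; the simulator presets therefore
treat reference-channel consumption as part of the drift being removed,
and real experiments should pick the reference with the smallest `k`.

## Fluxes

The biological exchange rate is the concentration derivative corrected
for the instrument's own consumption:

    v_g(t) = dC_g/dt + k_g · C_g(t) ,

positive for release into the medium, negative for uptake.  Derivatives
are central differences on a centered moving average (default window 30 s;
window 0 disables smoothing), with shrunken windows at the series edges
and third-order one-sided difference stencils there — second-order edge
formulas leave an O(k²Δt) bias on exponential decays that is large
compared to the `v ≈ 0` expected from a pure-leak segment.  Smoothing is
applied to concentrations before differentiation (configurable), not to
the rates.  Cumulative exchanges are trapezoidal running integrals zeroed
at a chosen origin (typically light-on).  Rates can be rescaled from
µmol L⁻¹ s⁻¹ to µmol (mg Chl)⁻¹ h⁻¹ given the chlorophyll density.

## Spectral unmixing

Electron-impact fragmentation spreads each gas over several channels
(CO₂ and N₂O share m/z 44; CO₂ puts 9.81 % of its base peak on m/z 28
under N₂; D₂ puts 1.59 % on the H₂ channel at m/z 2).  With the registry
patterns assembled into a mixing matrix `F` (base peak = 1), the observed
baseline-subtracted channel vector is `S ≈ F·x` and the per-species
signals `x ≥ 0` are recovered by nonnegative least squares per time
point, with the residual norm reported rather than silently absorbed.
Rank-deficient channel choices are rejected with the offending species
pair named.  The registry ships typical patterns; they depend on the ion
source and should be re-measured for quantitative overlap work.

## Isotope analyses

**¹⁸O₂/¹⁶O₂ partitioning.**  With the vessel spiked with highly enriched
¹⁸O₂, water splitting produces essentially pure ¹⁶O₂ (¹⁶O abundance
0.998 → 0.998² ≈ 99.6 % of water-derived O₂ is ¹⁶O¹⁶O) while uptake
consumes both isotopologues in proportion to their abundance and without
isotopic discrimination.  Then

    uptake    = v₁₈ (1 + C₁₆/C₁₈)
    evolution = v₁₆ − v₁₈ C₁₆/C₁₈
    net       = evolution + uptake = v₁₆ + v₁₈  (exact identity).

¹⁶O¹⁸O (m/z 34) is neglected under the high-enrichment assumption; the
`enrichment` output tracks the ¹⁸O₂ share so its erosion in long runs is
visible.  Points with no label left are masked, not extrapolated.

**H/D exchange.**  Hydrogenase turnover converts a D₂ spike to HD and H₂
in protonated water.  The deuterium atom fraction
τ = (C_D₂ + C_HD/2)/(C_D₂ + C_H₂ + C_HD) normalizes the H-atom appearance
rate, V_exch = (2·v_H₂ + v_HD)/τ, making the activity estimate
independent of the spike's size and enrichment.  When cells also evolve
H₂, an optional correction (off by default) subtracts the expected H-atom
share 2(1−τ) of net total-hydrogen production from the numerator and
reports its magnitude separately.  The H₂ channel is corrected for D₂'s
m/z 2 fragment before conversion.

**CA ¹⁸O-exchange.**  Carbonic anhydrase activity is read from the
unlabeling of a doubly-labeled ¹³C¹⁸O₂ spike (working on m/z 45/47/49
sidesteps the ambient-¹²CO₂ background at m/z 44).  The ¹⁸O content per
molecule, α = (2C₄₉ + C₄₇)/(C₄₉ + C₄₇ + C₄₅) ∈ [0, 2], decays as
a₁·e^(−θt); θ is fitted by nonlinear least squares seeded from a
log-linear fit, with θ ≥ 0 enforced and non-positive α trimmed.  α is
invariant to isotope-blind CO₂ consumption, so fixation does not bias θ;
the total-¹³C series (Σ) is emitted to audit that consumption.  An
optional linear cross-term subtraction handles ion-source recombination
of ¹⁸O₂ with C¹⁶O₂ into spurious m/z 47 (γ estimated from a biology-free
control; off by default).  In vivo the fitted θ aggregates all CAs plus
membrane transport; attributing it to compartments is out of scope.

**Ci affinity and partitioning.**  During light-driven Ci drawdown each
time point is a (C_CO₂, rate) sample, so a single run traces the whole
Michaelis–Menten curve; `fit_k_half` fits v = V_max·C/(K₁/₂ + C)
(Hanes-initialized, order-invariant, optional residual bootstrap CIs) on
raw or concentration-decile-binned pairs — binning compensates for the
unequal dwell times of an exponential-like depletion.  Carbonate
chemistry is two-species (CO₃²⁻ neglected, valid to pH ≈ 9):
HCO₃⁻/CO₂ = 10^(pH−pK₁) with pK₁ = 6.35 and uncatalyzed hydration
k_h = 0.036 s⁻¹ at 25 °C (literature reference values, configurable).
The disequilibrium partition takes total Ci uptake as net O₂/PQ (PQ
defaults to 1, configurable), reconstructs biological CO₂ uptake from the
measured net CO₂ flux minus the uncatalyzed supply k_d·HCO₃⁻ − k_h·CO₂,
and assigns the remainder to HCO₃⁻; the partition sums to the total
exactly and the supply flux is reported for auditing.  It refuses to run
when extracellular CA is declared present.

## The simulator

The virtual instrument integrates per-scenario gas dynamics
dC_g/dt = biology − k_g·C_g with fixed-step RK4 (0.1 s; the dynamics are
non-stiff at these time scales), applies injections as instantaneous
concentration steps and light-on as a step in the source term, then
synthesizes channels through the fragmentation matrix, multiplies by an
optional common-mode sinusoidal drift and adds per-channel Gaussian noise
with SD proportional to the instantaneous signal.  Preset protocol
timings and magnitudes: ¹⁸O₂ run with 5 min dark then 10 min light,
~250 µmol L⁻¹ of each O₂ isotopologue, gross evolution 0.15 and uptake
0.05 µmol L⁻¹ s⁻¹ at 20 µg Chl mL⁻¹; D₂ spike of 80 µmol L⁻¹ with
exchange constant 0.01 s⁻¹ (0 when uninduced); ¹³C¹⁸O₂ spike of
0.1 mmol L⁻¹ at 98 % atom enrichment after 1 min darkness, θ = 0.015 s⁻¹
induced; Ci depletion at K₁/₂ = 5 µmol L⁻¹ (air-grown, active CCM) vs
50 µmol L⁻¹ (high-CO₂-grown), V_max = 0.5 µmol L⁻¹ s⁻¹.  Sensitivities
5·10⁻¹⁰ A per µmol L⁻¹, baselines 10⁻¹¹ A, consumption 2·10⁻³ s⁻¹.  The
high-CO₂ preset starts from a larger DIC pool (600 vs 100 µmol L⁻¹) over
a longer run so the depletion spans both sides of its K₁/₂.

The ¹⁸O-exchange scenario moves ¹⁸O atoms one at a time
(C₄₉ → C₄₇ → C₄₅ at per-atom rate θ), which keeps the isotopologue
distribution binomial and makes α = 2p decay exactly exponentially — the
model the fit assumes.  The H/D scenario is the linear chain
D₂ → HD → H₂ at a common rate under proton excess, which has a closed-form
solution used as an independent oracle in the tests.

What the simulator does *not* model: the membrane/tubing response lag
(treated as a hardware design constraint, so simulated traces are sharper
than real ones around events), membrane aging, temperature dynamics,
vessel heterogeneity, and non-Gaussian detector noise.  Passing recovery
tests therefore certify the *calculus* — calibration inversion,
consumption correction, unmixing, the isotope algebra and the fits —
under the stated noise model, not robustness to instrument pathologies.

## Test and audit sizes

Recovery checks use 1 Hz traces of 7.5–30 min (450–1800 samples), 20
seeds at 1 % relative channel noise for the ¹⁸O₂ scenario, 100 seeds for
the α-fit robustness check (σ_α = 0.02), 5 seeds per growth condition for
the Ci-affinity contrast, and 1000 random mixtures for the unmixing
property.  Conservation audits (H-type atoms, total ¹³C, DIC) integrate
the simulator's own leak terms against the pool change at 10 Hz sampling
and hold to ~10⁻⁴–10⁻³ relative, the residual being dominated by the
single RK4 step that straddles an event discontinuity.

## Known limitations

* The first-order consumption model assumes a fresh, stable membrane; `k`
  should be re-estimated per run from an abiotic segment.
* Reference-gas normalization removes the reference's own leak along with
  the drift (see above).
* The N₂O/CO₂ overlap treatment is linear unmixing on tabulated patterns;
  strongly nonlinear source effects (space charge, saturation) are out of
  scope.
* Solubility, pK₁ and uncatalyzed kinetic constants are packaged
  reference values for fresh water at the tabulated temperatures, not
  instrument ground truth.
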