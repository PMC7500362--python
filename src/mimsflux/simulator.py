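"""Virtual MIMS instrument: ground-truth biology → noisy ion-current traces.

The simulator integrates per-scenario gas dynamics

    dC_g/dt = biology_g(C, t) − k_g·C_g

(first-order membrane consumption, injections as instantaneous
concentration steps) with fixed-step RK4, then synthesizes channel
currents through the fragmentation registry,

    S_c(t) = Σ_g F[c, g]·s_g·C_g(t) + b_c,

applies an optional multiplicative common-mode drift (slow sinusoid,
shared by all channels) and per-channel Gaussian noise with SD relative to
the instantaneous signal.  Each run emits the trace plus a
:class:`GroundTruth` sidecar carrying the true concentrations and the true
biological fluxes, so every analysis stage can be tested without an
instrument.

Four presets mirror the canonical closed-vessel protocols:

* ``s1_o2_isotope``  — ¹⁸O₂ spike, 5 min dark then light-on: gross O₂
  evolution (unlabeled, PSII) against isotope-blind uptake.
* ``s2_hd_exchange`` — D₂ spike under anaerobiosis; hydrogenase converts
  D₂ → HD → H₂ in a linear chain at rate ``k_ex``.
* ``s3_ca_unlabeling`` — doubly-labeled ¹³C¹⁸O₂ spike in darkness; CA
  exchanges ¹⁸O with water atom-by-atom at rate ``theta``, which keeps the
  isotopologue distribution binomial and makes α decay as a₁·e^(−θt).
* ``s4_ci_depletion`` — saturating light drives Michaelis–Menten Ci uptake
  until exhaustion, with two-species carbonate chemistry and an optional
  HCO₃⁻ transport share.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import SimulationError
from .registry import GasRegistry, fragmentation_intensity
from .trace import Event, TraceMeta, TraceSet

__all__ = ["InstrumentModel", "ScenarioSpec", "GroundTruth", "simulate", "preset", "PRESETS"]


@dataclass(frozen=True)
class InstrumentModel:
    """Linear per-gas signal model plus noise/drift parameters."""

    sensitivity: dict[str, float]  # A per (µmol/L), per species
    baseline: dict[int, float]  # A, per channel
    consumption: dict[str, float]  # k_g, s⁻¹, per species (absent → 0)
    noise_rel: float = 0.0  # Gaussian SD relative to instantaneous signal
    drift_amplitude: float = 0.0  # multiplicative sinusoid amplitude
    drift_period: float = 600.0  # s

    def k(self, species: str) -> float:
        return self.consumption.get(species, 0.0)


@dataclass
class ScenarioSpec:
    """Complete description of one simulated experiment."""

    scenario: str  # s1_o2_isotope | s2_hd_exchange | s3_ca_unlabeling | s4_ci_depletion | custom
    duration: float  # s
    species: list[str]  # state variables (may include unobserved, e.g. HCO3)
    initial: dict[str, float]  # µmol L⁻¹
    channels: list[int]  # observed m/z
    instrument: InstrumentModel
    params: dict[str, float] = field(default_factory=dict)
    events: list[Event] = field(default_factory=list)
    injections: dict[str, dict[str, float]] = field(default_factory=dict)  # label → Δconc
    dt: float = 0.1  # integration step, s
    sample_dt: float = 1.0  # trace sampling interval, s
    meta: TraceMeta = field(default_factory=TraceMeta)
    seed: int = 0

    def validate(self) -> None:
        if self.dt <= 0 or self.sample_dt <= 0:
            raise SimulationError("dt and sample_dt must be > 0")
        if self.dt > self.duration:
            raise SimulationError("integration step exceeds duration")
        for g, c in self.initial.items():
            if c < 0:
                raise SimulationError(f"initial concentration of {g} negative")
        for label in self.injections:
            if not any(ev.label == label for ev in self.events):
                raise SimulationError(f"injection {label!r} has no event marker")


@dataclass
class GroundTruth:
    """True concentrations and biological fluxes at the trace's sample times."""

    time: np.ndarray
    conc: dict[str, np.ndarray]
    flux: dict[str, np.ndarray]  # biology only (what dC/dt + kC recovers)
    extra: dict[str, np.ndarray] = field(default_factory=dict)
    params: dict[str, float] = field(default_factory=dict)
    light: np.ndarray | None = None


# ---------------------------------------------------------------- biology

def _bio_s1(y: dict[str, float], t: float, p: dict, light: float) -> dict[str, float]:
    """Gross evolution E (unlabeled only, in light) + isotope-blind uptake U."""
    c16, c18 = y["O2"], y["18O2"]
    tot = c16 + c18
    if tot > 0:
        u = p["U"]
        u16, u18 = u * c16 / tot, u * c18 / tot
    else:
        u16 = u18 = 0.0
    return {"O2": p["E"] * light - u16, "18O2": -u18}


def _bio_s2(y: dict[str, float], t: float, p: dict, light: float) -> dict[str, float]:
    """Linear exchange chain D2 →(k_ex) HD →(k_ex) H2 under proton excess."""
    k = p["k_ex"]
    return {
        "D2": -k * y["D2"],
        "HD": k * y["D2"] - k * y["HD"],
        "H2": k * y["HD"],
    }


def _bio_s3(y: dict[str, float], t: float, p: dict, light: float) -> dict[str, float]:
    """Atom-level ¹⁸O exchange: each ¹⁸O swaps with water at rate theta."""
    th = p["theta"]
    return {
        "13C18O2": -2.0 * th * y["13C18O2"],
        "13C18O16O": 2.0 * th * y["13C18O2"] - th * y["13C18O16O"],
        "13CO2": th * y["13C18O16O"],
    }


def _bio_s4(y: dict[str, float], t: float, p: dict, light: float) -> dict[str, float]:
    """MM Ci uptake (CO₂-controlled) + uncatalyzed carbonate interconversion."""
    co2, hco3 = y["CO2"], y["HCO3"]
    upt = light * p["V_max"] * co2 / (p["K_half"] + co2) if co2 > 0 else 0.0
    share = p.get("hco3_share", 0.0)
    chem = p["k_d"] * hco3 - p["k_h"] * co2
    return {
        "CO2": chem - (1.0 - share) * upt,
        "HCO3": -chem - share * upt,
        "O2": p.get("pq", 1.0) * upt,
    }


def _bio_zero(y: dict[str, float], t: float, p: dict, light: float) -> dict[str, float]:
    return {g: 0.0 for g in y}


_BIOLOGY = {
    "s1_o2_isotope": _bio_s1,
    "s2_hd_exchange": _bio_s2,
    "s3_ca_unlabeling": _bio_s3,
    "s4_ci_depletion": _bio_s4,
    "custom": _bio_zero,
}


def _s4_extra(y: dict[str, float], p: dict, light: float) -> dict[str, float]:
    co2 = y["CO2"]
    upt = light * p["V_max"] * co2 / (p["K_half"] + co2) if co2 > 0 else 0.0
    share = p.get("hco3_share", 0.0)
    return {
        "total_ci_uptake": upt,
        "co2_uptake": (1.0 - share) * upt,
        "hco3_uptake": share * upt,
    }


# --------------------------------------------------------------- integrator

def simulate(spec: ScenarioSpec, registry: GasRegistry) -> tuple[TraceSet, GroundTruth]:
    """Run the forward model; returns ``(trace, ground_truth)``.

    Deterministic for a fixed seed.  Raises :class:`SimulationError` if a
    concentration goes negative (advice: reduce ``dt``).
    """
    spec.validate()
    if spec.scenario not in _BIOLOGY:
        raise SimulationError(
            f"unknown scenario {spec.scenario!r}; known: {sorted(_BIOLOGY)}"
        )
    bio = _BIOLOGY[spec.scenario]
    p = dict(spec.params)
    if spec.scenario == "s4_ci_depletion":
        p.setdefault("k_h", 0.036)
        p.setdefault("k_d", p["k_h"] * 10.0 ** (p.get("pK1", 6.35) - spec.meta.pH))

    light_time = next((ev.time for ev in spec.events if ev.label == "light_on"), None)

    def light_at(t: float) -> float:
        return 1.0 if (light_time is not None and t >= light_time) else 0.0

    species = list(spec.species)
    kvec = np.array([spec.instrument.k(g) for g in species])
    y = np.array([spec.initial.get(g, 0.0) for g in species], dtype=float)

    def deriv(t: float, yv: np.ndarray) -> np.ndarray:
        state = dict(zip(species, yv))
        b = bio(state, t, p, light_at(t))
        return np.array([b.get(g, 0.0) for g in species]) - kvec * yv

    n_steps = int(round(spec.duration / spec.dt))
    every = max(int(round(spec.sample_dt / spec.dt)), 1)
    inj_at: dict[int, dict[str, float]] = {}
    for label, delta in spec.injections.items():
        t_ev = next(ev.time for ev in spec.events if ev.label == label)
        inj_at.setdefault(int(round(t_ev / spec.dt)), {}).update(delta)

    times, concs, fluxes, extras, lights = [], [], [], [], []

    def record(step: int, t: float) -> None:
        if step % every:
            return
        state = dict(zip(species, y))
        lt = light_at(t)
        b = bio(state, t, p, lt)
        times.append(t)
        concs.append(y.copy())
        fluxes.append(np.array([b.get(g, 0.0) for g in species]))
        if spec.scenario == "s4_ci_depletion":
            extras.append(_s4_extra(state, p, lt))
        lights.append(lt)

    h = spec.dt
    for step in range(n_steps + 1):
        t = step * h
        if step in inj_at:
            for g, d in inj_at[step].items():
                y[species.index(g)] += d
        record(step, t)
        if step == n_steps:
            break
        k1 = deriv(t, y)
        k2 = deriv(t + h / 2, y + h / 2 * k1)
        k3 = deriv(t + h / 2, y + h / 2 * k2)
        k4 = deriv(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if np.any(y < -1e-9):
            g = species[int(np.argmin(y))]
            raise SimulationError(
                f"concentration of {g} went negative at t={t + h:.1f}s; "
                "use a smaller integration step or gentler rates"
            )
        y = np.maximum(y, 0.0)

    tarr = np.array(times)
    C = np.array(concs)  # (n, ns)
    V = np.array(fluxes)
    conc = {g: C[:, j] for j, g in enumerate(species)}
    flux = {g: V[:, j] for j, g in enumerate(species)}
    extra = (
        {k: np.array([e[k] for e in extras]) for k in extras[0]} if extras else {}
    )

    # ----- signal synthesis
    inst = spec.instrument
    rng = np.random.default_rng(spec.seed)
    drift = 1.0 + inst.drift_amplitude * np.sin(2 * np.pi * tarr / inst.drift_period)
    channels: dict[int, np.ndarray] = {}
    for c in spec.channels:
        S = np.full(tarr.shape, inst.baseline.get(c, 0.0))
        for g in species:
            s_g = inst.sensitivity.get(g)
            if s_g is None:
                continue
            f = fragmentation_intensity(registry, g, c) / 100.0
            if f:
                S = S + f * s_g * conc[g]
        S = S * drift
        if inst.noise_rel > 0:
            S = S + rng.normal(0.0, inst.noise_rel * np.abs(S))
        channels[c] = S

    trace = TraceSet(tarr, channels, meta=spec.meta, events=list(spec.events))
    truth = GroundTruth(
        time=tarr, conc=conc, flux=flux, extra=extra,
        params=dict(p), light=np.array(lights),
    )
    return trace, truth


# ----------------------------------------------------------------- presets

def _instrument(species: list[str], channels: list[int], k: float = 2e-3,
                **kw) -> InstrumentModel:
    return InstrumentModel(
        sensitivity={g: 5e-10 for g in species},
        baseline={c: 1e-11 for c in channels},
        consumption={g: k for g in species},
        **kw,
    )


def _preset_s1(seed: int) -> ScenarioSpec:
    species = ["O2", "18O2"]
    channels = [32, 36]
    return ScenarioSpec(
        scenario="s1_o2_isotope",
        duration=900.0,
        species=species,
        initial={"O2": 250.0, "18O2": 250.0},  # air O2 + injected label
        channels=channels,
        instrument=_instrument(species, channels),
        params={"E": 0.15, "U": 0.05},  # µmol L⁻¹ s⁻¹
        events=[Event(0.0, "vessel_closed"), Event(300.0, "light_on")],
        meta=TraceMeta(25.0, 1.5, 7.2, 20.0),
        seed=seed,
    )


def _preset_s2(seed: int) -> ScenarioSpec:
    species = ["D2", "HD", "H2"]
    channels = [2, 3, 4]
    return ScenarioSpec(
        scenario="s2_hd_exchange",
        duration=600.0,
        species=species,
        initial={"D2": 0.0, "HD": 0.0, "H2": 0.0},
        channels=channels,
        instrument=_instrument(species, channels),
        params={"k_ex": 0.01},  # s⁻¹; set 0 for an uninduced culture
        events=[Event(0.0, "vessel_closed"), Event(60.0, "d2_injection")],
        injections={"d2_injection": {"D2": 80.0}},
        meta=TraceMeta(25.0, 1.5, 7.2, 20.0),
        seed=seed,
    )


def _preset_s3(seed: int, p0: float = 0.98, total: float = 100.0) -> ScenarioSpec:
    species = ["13C18O2", "13C18O16O", "13CO2"]
    channels = [45, 47, 49]
    return ScenarioSpec(
        scenario="s3_ca_unlabeling",
        duration=460.0,
        species=species,
        initial={g: 0.0 for g in species},
        channels=channels,
        instrument=_instrument(species, channels),
        params={"theta": 0.015, "p0": p0},  # θ s⁻¹; uninduced ≈ 10× slower
        events=[Event(0.0, "vessel_closed"), Event(60.0, "injection")],
        injections={
            "injection": {
                "13C18O2": p0**2 * total,
                "13C18O16O": 2 * p0 * (1 - p0) * total,
                "13CO2": (1 - p0) ** 2 * total,
            }
        },
        meta=TraceMeta(25.0, 1.5, 7.2, 20.0),
        seed=seed,
    )


def _preset_s4(seed: int, grown: str = "air") -> ScenarioSpec:
    # air-grown cells (active CCM): K_1/2 = 5 µM; high-CO2-grown: 50 µM
    if grown == "air":
        k_half, dic0, duration = 5.0, 100.0, 900.0
    else:
        k_half, dic0, duration = 50.0, 600.0, 1800.0
    pH, pK1 = 7.2, 6.35
    r = 10.0 ** (pH - pK1)
    co2_0 = dic0 / (1 + r)
    species = ["O2", "CO2", "HCO3"]
    channels = [32, 44]
    inst = InstrumentModel(
        sensitivity={"O2": 5e-10, "CO2": 5e-10},
        baseline={c: 1e-11 for c in channels},
        consumption={"O2": 2e-3, "CO2": 2e-3},  # HCO3⁻ is non-volatile: no leak
    )
    return ScenarioSpec(
        scenario="s4_ci_depletion",
        duration=duration,
        species=species,
        initial={"O2": 250.0, "CO2": co2_0, "HCO3": dic0 - co2_0},
        channels=channels,
        instrument=inst,
        params={
            "V_max": 0.5, "K_half": k_half, "hco3_share": 0.0,
            "pq": 1.0, "k_h": 0.036, "pK1": pK1,
        },
        events=[Event(0.0, "vessel_closed"), Event(30.0, "light_on")],
        meta=TraceMeta(25.0, 1.5, pH, 20.0),
        seed=seed,
    )


PRESETS = {
    "s1_o2_isotope": _preset_s1,
    "s2_hd_exchange": _preset_s2,
    "s3_ca_unlabeling": _preset_s3,
    "s4_ci_depletion": _preset_s4,
}


def preset(
    name: str,
    seed: int = 0,
    *,
    params: dict[str, float] | None = None,
    noise_rel: float | None = None,
    drift_amplitude: float | None = None,
    drift_period: float | None = None,
    **preset_kwargs,
) -> ScenarioSpec:
    """A documented :class:`ScenarioSpec` mimicking a standard protocol.

    ``params`` overrides biological parameters (e.g. ``{"k_ex": 0.0}`` for
    an uninduced culture, ``{"hco3_share": 0.7}`` for preferential HCO₃⁻
    transport); ``noise_rel``/``drift_*`` override instrument parameters.
    ``s4_ci_depletion`` accepts ``grown="air"|"co2"``.
    """
    try:
        factory = PRESETS[name]
    except KeyError:
        raise SimulationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    spec = factory(seed, **preset_kwargs)
    if params:
        spec.params.update(params)
        # keep s3 injections consistent with a changed atom enrichment
        if name == "s3_ca_unlabeling" and "p0" in params:
            p0 = params["p0"]
            total = sum(spec.injections["injection"].values())
            spec.injections["injection"] = {
                "13C18O2": p0**2 * total,
                "13C18O16O": 2 * p0 * (1 - p0) * total,
                "13CO2": (1 - p0) ** 2 * total,
            }
    inst = spec.instrument
    updates = {}
    if noise_rel is not None:
        updates["noise_rel"] = noise_rel
    if drift_amplitude is not None:
        updates["drift_amplitude"] = drift_amplitude
    if drift_period is not None:
        updates["drift_period"] = drift_period
    if updates:
        spec.instrument = replace(inst, **updates)
    return spec


def truth_calibration(spec: ScenarioSpec):
    """The exact :class:`~mimsflux.calibrate.CalibrationModel` of a scenario.

    Builds the calibration the instrument model implies (sensitivity,
    baseline on each species' base channel, consumption constant) — the
    construction inverse used when testing analysis stages in isolation.
    """
    from .calibrate import CalEntry, CalibrationModel
    from .registry import load_gas_registry

    reg = load_gas_registry()
    entries = {}
    for g, s in spec.instrument.sensitivity.items():
        mz = reg[g].base_peak_mz
        entries[g] = CalEntry(
            sensitivity=s,
            baseline=spec.instrument.baseline.get(mz, 0.0),
            consumption=spec.instrument.k(g),
        )
    return CalibrationModel(entries)
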