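"""Signal calibration: currents → concentrations, drift and consumption.

The instrument model is linear per gas: on its base-peak channel a species
``g`` contributes ``S_g(t) = s_g·C_g(t) + b_g`` with sensitivity ``s_g``
(A per µmol L⁻¹) and baseline ``b_g`` (A).  The mass spectrometer itself
consumes dissolved gas through the membrane at a first-order rate
``k_g·C_g`` (the leak is linear in concentration), which the flux engine
adds back when converting concentration changes to biological rates.

Common-mode signal drift (membrane permeability fluctuations, source
drift) is removed by normalizing every channel to an inert reference gas
(N₂ or Ar): any multiplicative disturbance shared by all channels cancels
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import CalibrationError, NormalizationError
from .registry import GasRegistry, equilibrium_concentration
from .series import ConcentrationSeries
from .trace import TraceSet

__all__ = [
    "CalEntry",
    "CalibrationModel",
    "ConsumptionFit",
    "normalize_to_reference",
    "fit_two_point_calibration",
    "estimate_consumption_constant",
    "signal_to_concentration",
]

#: default quasi-steadiness bound for calibration segments (relative SD)
STEADINESS_RTOL = 0.01


@dataclass
class CalEntry:
    """Calibration for one species on its base-peak channel."""

    sensitivity: float  # A per (µmol/L), > 0
    baseline: float  # A, >= 0
    consumption: float = 0.0  # k, s^-1, >= 0
    noise_sd: float = 0.0  # baseline noise SD, A
    segments: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise CalibrationError(f"sensitivity must be > 0, got {self.sensitivity}")
        if self.baseline < 0:
            raise CalibrationError(f"baseline must be >= 0, got {self.baseline}")
        if self.consumption < 0:
            raise CalibrationError(f"consumption must be >= 0, got {self.consumption}")


@dataclass
class CalibrationModel:
    """Per-species calibration entries plus the reference-gas drift anchor."""

    entries: dict[str, CalEntry] = field(default_factory=dict)
    reference_species: str | None = None
    reference_anchor: float | None = None  # amperes at anchor time

    def __getitem__(self, species: str) -> CalEntry:
        try:
            return self.entries[species]
        except KeyError:
            raise CalibrationError(
                f"no calibration for species {species!r}; calibrated: "
                f"{sorted(self.entries)}"
            ) from None

    def __contains__(self, species: str) -> bool:
        return species in self.entries

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "entries": {k: asdict(v) for k, v in self.entries.items()},
            "reference_species": self.reference_species,
            "reference_anchor": self.reference_anchor,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        raw = json.loads(Path(path).read_text())
        entries = {
            k: CalEntry(
                sensitivity=v["sensitivity"],
                baseline=v["baseline"],
                consumption=v.get("consumption", 0.0),
                noise_sd=v.get("noise_sd", 0.0),
                segments={kk: tuple(vv) for kk, vv in v.get("segments", {}).items()},
            )
            for k, v in raw["entries"].items()
        }
        return cls(entries, raw.get("reference_species"), raw.get("reference_anchor"))


def normalize_to_reference(
    trace: TraceSet,
    reference_mz: int,
    anchor_time: float | None = None,
) -> TraceSet:
    """Divide out common-mode drift using an inert reference channel.

    Every channel is multiplied, sample by sample, by
    ``anchor / S_ref(t)`` where ``anchor`` is the reference signal at
    ``anchor_time`` (default: first sample).  The reference channel itself
    becomes constant at the anchor value, and the operation is idempotent.

    Raises :class:`NormalizationError` if the reference signal is not
    strictly positive everywhere.
    """
    ref = trace.channel(reference_mz)
    if np.any(ref <= 0):
        i = int(np.argmax(ref <= 0))
        raise NormalizationError(
            f"reference channel mz{reference_mz} non-positive at t={trace.time[i]}"
        )
    if anchor_time is None:
        anchor = ref[0]
    else:
        anchor = float(np.interp(anchor_time, trace.time, ref))
    factor = anchor / ref
    return trace.with_channels({mz: s * factor for mz, s in trace.channels.items()})


def _segment_mean(
    trace: TraceSet,
    mz: int,
    segment: tuple[float, float],
    steadiness_rtol: float,
    what: str,
) -> float:
    mask = trace.window_mask(*segment)
    if mask.sum() < 2:
        raise CalibrationError(f"{what} segment {segment} has < 2 samples")
    vals = trace.channel(mz)[mask]
    mean = float(vals.mean())
    if mean != 0 and float(vals.std()) / abs(mean) > steadiness_rtol:
        raise CalibrationError(
            f"{what} segment {segment} on mz{mz} not quasi-steady "
            f"(relative SD {vals.std() / abs(mean):.3g} > {steadiness_rtol})"
        )
    return mean


def fit_two_point_calibration(
    trace: TraceSet,
    registry: GasRegistry,
    air_segment: tuple[float, float] | None,
    zero_segment: tuple[float, float],
    species: list[str],
    *,
    spiked: dict[str, tuple[tuple[float, float], float]] | None = None,
    steadiness_rtol: float = STEADINESS_RTOL,
    total_pressure_atm: float = 1.0,
) -> CalibrationModel:
    """Two-point (air + zero) calibration on each species' base channel.

    ``b_g`` is the mean signal in the zero segment (after inert flush);
    ``s_g = (mean air signal − b_g) / C_air,g`` with ``C_air,g`` the
    equilibrium concentration at the trace temperature and the species'
    atmospheric partial pressure.  Species absent from air need a
    ``spiked`` entry ``name → ((t0, t1), known_concentration)`` instead.

    Both segments must be quasi-steady (relative SD below
    ``steadiness_rtol``).  Consumption constants are fitted separately
    (:func:`estimate_consumption_constant`) and filled in afterwards.
    """
    spiked = spiked or {}
    model = CalibrationModel()
    missing: list[str] = []
    for name in species:
        sp = registry[name]
        mz = sp.base_peak_mz
        b = _segment_mean(trace, mz, zero_segment, steadiness_rtol, "zero")
        zmask = trace.window_mask(*zero_segment)
        noise_sd = float(trace.channel(mz)[zmask].std())
        if name in spiked:
            seg, conc = spiked[name]
            if conc <= 0:
                raise CalibrationError(f"{name}: spiked concentration must be > 0")
            high = _segment_mean(trace, mz, seg, steadiness_rtol, "spiked")
            c_ref = conc
            segs = {"zero": tuple(zero_segment), "spiked": tuple(seg)}
        else:
            p_air = sp.air_partial_pressure_atm * total_pressure_atm
            c_ref = (
                equilibrium_concentration(
                    sp, trace.meta.temperature_C, p_air, registry=registry
                )
                if p_air > 0
                else 0.0
            )
            if c_ref <= 0 or air_segment is None:
                missing.append(name)
                continue
            high = _segment_mean(trace, mz, air_segment, steadiness_rtol, "air")
            segs = {"zero": tuple(zero_segment), "air": tuple(air_segment)}
        s = (high - b) / c_ref
        if s <= 0:
            raise CalibrationError(
                f"{name}: non-positive fitted sensitivity ({s:.3g} A per µmol/L)"
            )
        model.entries[name] = CalEntry(
            sensitivity=s, baseline=b, noise_sd=noise_sd, segments=segs
        )
    if missing:
        raise CalibrationError(
            f"species {missing} are absent from air (or no air segment given); "
            "provide a spiked segment of known concentration for them"
        )
    return model


@dataclass(frozen=True)
class ConsumptionFit:
    """Result of a consumption-constant fit (k in s⁻¹)."""

    k: float
    stderr: float
    clamped: bool  # True when the raw estimate was negative and clamped to 0
    n: int


def estimate_consumption_constant(
    conc: ConcentrationSeries,
    species: str,
    segment: tuple[float, float],
) -> ConsumptionFit:
    """First-order membrane-consumption constant from an abiotic segment.

    Over a window where the instrument leak is the only sink,
    ``dC/dt = −kC``, so ``k`` is minus the least-squares slope of
    ``ln C`` against ``t``.  A negative estimate (rising signal) is clamped
    to 0 with ``clamped=True`` rather than silently.

    The estimate is invariant to rescaling C by any positive constant.
    """
    mask = conc.window_mask(*segment)
    if mask.sum() < 3:
        raise CalibrationError(f"segment {segment}: need >= 3 samples, got {mask.sum()}")
    c = conc[species][mask]
    if np.any(c <= 0):
        raise CalibrationError(
            f"{species}: non-positive concentration inside segment {segment}"
        )
    t = conc.time[mask]
    res = stats.linregress(t, np.log(c))
    k = -float(res.slope)
    clamped = k < 0
    return ConsumptionFit(
        k=max(k, 0.0), stderr=float(res.stderr), clamped=clamped, n=int(mask.sum())
    )


def signal_to_concentration(
    trace: TraceSet,
    cal: CalibrationModel,
    registry: GasRegistry,
    species: list[str] | None = None,
    *,
    signals: dict[str, np.ndarray] | None = None,
) -> ConcentrationSeries:
    """Invert the linear signal model: ``C_g(t) = (S_g(t) − b_g)/s_g``.

    By default each species is read from its base-peak channel; pass
    ``signals`` (e.g. the output of spectral unmixing, baseline already
    removed — in that case the entry baseline is not subtracted again) to
    override.

    Small negative concentrations (within 3× the baseline-noise SD mapped
    into concentration units) are clipped to zero and counted
    (``clipped_counts``); more negative excursions are left in place and
    counted in ``flagged_counts`` as possible model misfit.
    """
    names = species if species is not None else sorted(cal.entries)
    data: dict[str, np.ndarray] = {}
    clipped: dict[str, int] = {}
    flagged: dict[str, int] = {}
    for name in names:
        entry = cal[name]
        if signals is not None and name in signals:
            c = np.asarray(signals[name], dtype=float) / entry.sensitivity
        else:
            mz = registry[name].base_peak_mz
            c = (trace.channel(mz) - entry.baseline) / entry.sensitivity
        tol = 3.0 * entry.noise_sd / entry.sensitivity
        small_neg = (c < 0) & (c >= -tol)
        clipped[name] = int(small_neg.sum())
        flagged[name] = int(((c < -tol)).sum())
        c = c.copy()
        c[small_neg] = 0.0
        data[name] = c
    return ConcentrationSeries(
        trace.time.copy(), data, provenance="calibrated",
        clipped_counts=clipped, flagged_counts=flagged,
    )
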