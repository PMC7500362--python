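"""Inorganic-carbon affinity (K₁/₂) and CO₂ vs HCO₃⁻ uptake partitioning.

During photosynthetic depletion of inorganic carbon (Ci) in a closed,
illuminated vessel, each time point supplies a (CO₂ concentration, rate)
pair, so a single run traces out the whole rate-vs-substrate curve.  A
Michaelis–Menten fit, v = V_max·C/(K₁/₂ + C), summarizes the apparent
affinity; an active carbon-concentrating mechanism shows up as a roughly
tenfold lower K₁/₂.

Two-species carbonate chemistry (carbonate neglected, valid to pH ≈ 9):
HCO₃⁻/CO₂ = 10^(pH − pK₁).  The uncatalyzed interconversion is slow
(hydration k_h ≈ 0.036 s⁻¹ at 25 °C), so preferential uptake of one
species drives a measurable disequilibrium — the basis for partitioning
net Ci uptake into CO₂ and HCO₃⁻ components from simultaneous O₂ and CO₂
traces.  The method is invalid when extracellular CA short-circuits the
disequilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import AnalysisError
from .series import ConcentrationSeries, FluxSeries

__all__ = [
    "DICState",
    "CiAffinityResult",
    "speciate_dic",
    "depletion_curve",
    "fit_k_half",
    "bicarbonate_uptake",
]

PK1_DEFAULT = 6.35  # apparent first dissociation constant of CO2(aq), fresh water
KH_DEFAULT = 0.036  # s^-1, uncatalyzed CO2 hydration at 25 °C (reference data)


@dataclass(frozen=True)
class DICState:
    """Two-species dissolved inorganic carbon state at fixed pH."""

    dic: float  # µmol L⁻¹
    pH: float
    pK1: float = PK1_DEFAULT
    hydration_rate_constant: float = KH_DEFAULT  # k_h, s⁻¹

    @property
    def co2(self) -> float:
        r = 10.0 ** (self.pH - self.pK1)
        return self.dic / (1.0 + r)

    @property
    def hco3(self) -> float:
        return self.dic - self.co2

    @property
    def dehydration_rate_constant(self) -> float:
        """Effective first-order HCO₃⁻ → CO₂ constant at this pH.

        Chosen so the uncatalyzed kinetics are at equilibrium when
        HCO₃⁻/CO₂ = 10^(pH − pK₁): k_d = k_h·10^(pK₁ − pH).
        """
        return self.hydration_rate_constant * 10.0 ** (self.pK1 - self.pH)


def speciate_dic(dic: float, pH: float, pK1: float = PK1_DEFAULT) -> tuple[float, float]:
    """Split total DIC into (CO₂, HCO₃⁻) at a given pH.

    Henderson–Hasselbalch with carbonate neglected (two-species model,
    documented validity pH ≲ 9): HCO₃⁻/CO₂ = 10^(pH − pK₁).  Conserves
    DIC exactly.
    """
    if dic < 0:
        raise ValueError(f"DIC must be >= 0, got {dic}")
    if not (4.0 <= pH <= 10.0):
        raise ValueError(f"pH {pH} outside supported range [4, 10]")
    r = 10.0 ** (pH - pK1)
    co2 = dic / (1.0 + r)
    return co2, dic - co2


def depletion_curve(
    conc: ConcentrationSeries,
    flux: FluxSeries,
    *,
    conc_species: str = "CO2",
    rate_species: str = "O2",
    window: tuple[float, float] | None = None,
    n_bins: int = 0,
    min_bin_count: int = 3,
    monotone_rtol: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (C_CO₂, rate) samples from a light-driven depletion phase.

    The window (default: whole series) must show monotonically decreasing
    CO₂ up to a relative tolerance ``monotone_rtol`` of its range; a
    non-depleting trace raises an error advising the protocol.  With
    ``n_bins`` > 0 the pairs are averaged within concentration-decile-style
    bins and bins with fewer than ``min_bin_count`` samples are dropped.
    """
    mask = (
        conc.window_mask(*window) if window is not None
        else np.ones(conc.time.size, dtype=bool)
    )
    c = conc[conc_species][mask]
    v = flux[rate_species][mask]
    if c.size < 5:
        raise AnalysisError("depletion window has fewer than 5 samples")
    span = float(c.max() - c.min())
    if span <= 0 or np.any(np.diff(c) > monotone_rtol * span):
        raise AnalysisError(
            f"{conc_species} is not depleting over the window; run the "
            "light-driven drawdown protocol (close the vessel, saturating "
            "light, record until Ci exhaustion)"
        )
    if n_bins <= 0:
        return c, v
    edges = np.quantile(c, np.linspace(0, 1, n_bins + 1))
    cb, vb = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (c >= lo) & (c <= hi)
        if sel.sum() >= min_bin_count:
            cb.append(float(c[sel].mean()))
            vb.append(float(v[sel].mean()))
    return np.array(cb), np.array(vb)


@dataclass
class CiAffinityResult:
    """Michaelis–Menten fit of a depletion curve."""

    K_half: float  # µmol L⁻¹
    V_max: float
    which_rate: str
    residual_rms: float
    n: int
    not_saturating: bool  # True when max C < fitted K_half
    ci_K_half: tuple[float, float] | None = None
    ci_V_max: tuple[float, float] | None = None
    pairs: tuple[np.ndarray, np.ndarray] | None = None


def fit_k_half(
    C: np.ndarray,
    v: np.ndarray,
    *,
    which_rate: str = "net_O2",
    n_bootstrap: int = 0,
    seed: int = 0,
) -> CiAffinityResult:
    """Fit v = V_max·C/(K₁/₂ + C) to paired depletion samples.

    Initialized from the Hanes linearization (C/v vs C); order-invariant
    in the samples.  ``n_bootstrap`` > 0 adds residual-bootstrap 95 %
    confidence intervals.  A fit whose K₁/₂ exceeds the sampled
    concentration range is flagged ``not_saturating`` rather than rejected.
    """
    C = np.asarray(C, float)
    v = np.asarray(v, float)
    sel = np.isfinite(C) & np.isfinite(v) & (C >= 0)
    C, v = C[sel], v[sel]
    if np.unique(np.round(C, 12)).size < 5:
        raise AnalysisError("need >= 5 distinct concentration levels for the fit")

    def mm(c, vmax, k):
        return vmax * c / (k + c)

    pos = (C > 0) & (v > 0)
    if pos.sum() >= 2:
        # Hanes: C/v = C/Vmax + K/Vmax
        slope, intercept = np.polyfit(C[pos], C[pos] / v[pos], 1)
        vmax0 = 1.0 / slope if slope > 0 else float(v.max())
        k0 = intercept * vmax0 if intercept > 0 else float(np.median(C))
    else:
        vmax0, k0 = float(v.max()), float(np.median(C))
    popt, _ = curve_fit(
        mm, C, v, p0=[max(vmax0, 1e-12), max(k0, 1e-12)],
        bounds=([0, 0], [np.inf, np.inf]), maxfev=20000,
    )
    vmax, k = float(popt[0]), float(popt[1])
    resid = v - mm(C, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))

    ci_k = ci_v = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        ks, vs = [], []
        fitted = mm(C, *popt)
        for _ in range(n_bootstrap):
            vb = fitted + rng.choice(resid, size=resid.size, replace=True)
            try:
                pb, _ = curve_fit(
                    mm, C, vb, p0=[vmax, k],
                    bounds=([0, 0], [np.inf, np.inf]), maxfev=5000,
                )
            except RuntimeError:
                continue
            vs.append(pb[0])
            ks.append(pb[1])
        if ks:
            ci_k = tuple(np.percentile(ks, [2.5, 97.5]))
            ci_v = tuple(np.percentile(vs, [2.5, 97.5]))

    return CiAffinityResult(
        K_half=k, V_max=vmax, which_rate=which_rate, residual_rms=rms,
        n=C.size, not_saturating=bool(C.max() < k),
        ci_K_half=ci_k, ci_V_max=ci_v, pairs=(C, v),
    )


@dataclass
class BicarbonateUptakeResult:
    """Disequilibrium partition of net Ci uptake into CO₂ and HCO₃⁻."""

    time: np.ndarray
    total_ci_uptake: np.ndarray  # µmol L⁻¹ s⁻¹ (positive = uptake)
    co2_uptake: np.ndarray
    hco3_uptake: np.ndarray
    chemical_co2_supply: np.ndarray  # uncatalyzed k_d·HCO₃ − k_h·CO₂ flux
    pq: float


def bicarbonate_uptake(
    net_o2: FluxSeries,
    net_co2: FluxSeries,
    co2: np.ndarray,
    hco3: np.ndarray,
    *,
    pH: float,
    pK1: float = PK1_DEFAULT,
    k_h: float = KH_DEFAULT,
    pq: float = 1.0,
    extracellular_ca: bool = False,
    o2_species: str = "O2",
    co2_species: str = "CO2",
) -> BicarbonateUptakeResult:
    """Partition net Ci uptake into CO₂ and HCO₃⁻ via the disequilibrium method.

    Total Ci uptake is taken as net O₂ production divided by the
    photosynthetic quotient PQ.  The CO₂ budget in the medium is
    ``v_CO2 = chemical_supply − co2_uptake`` with the uncatalyzed supply
    ``k_d·HCO₃⁻ − k_h·CO₂`` (k_d = k_h·10^(pK₁−pH)); the HCO₃⁻ uptake is
    the remainder, so the partition sums to the total exactly.  The supply
    flux is reported so the disequilibrium assumption can be audited.

    Refuses to run when ``extracellular_ca`` is declared: external CA
    equilibrates the species and destroys the disequilibrium signal.
    """
    if extracellular_ca:
        raise AnalysisError(
            "disequilibrium partitioning is invalid in the presence of "
            "extracellular carbonic anhydrase: it re-equilibrates CO2 and "
            "HCO3- faster than the uncatalyzed kinetics assumed here"
        )
    if pq <= 0:
        raise ValueError(f"PQ must be > 0, got {pq}")
    co2 = np.asarray(co2, float)
    hco3 = np.asarray(hco3, float)
    k_d = k_h * 10.0 ** (pK1 - pH)
    chem = k_d * hco3 - k_h * co2
    total_uptake = net_o2[o2_species] / pq
    co2_uptake = chem - net_co2[co2_species]
    hco3_uptake = total_uptake - co2_uptake
    return BicarbonateUptakeResult(
        time=net_o2.time,
        total_ci_uptake=total_uptake,
        co2_uptake=co2_uptake,
        hco3_uptake=hco3_uptake,
        chemical_co2_supply=chem,
        pq=pq,
    )
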