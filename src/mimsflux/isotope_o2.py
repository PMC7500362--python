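"""¹⁸O₂/¹⁶O₂ partitioning of photosynthetic O₂ exchange.

With the vessel spiked with highly enriched ¹⁸O₂, water splitting by PSII
produces essentially pure ¹⁶O₂ (¹⁶O natural abundance 0.998, so O₂ from
water is ¹⁶O¹⁶O at 0.998² ≈ 99.6 %), while uptake consumes both
isotopologues blindly in proportion to their abundance.  From the
consumption-corrected exchange rates v₁₆, v₁₈ and concentrations C₁₆, C₁₈:

    uptake(t)    = v₁₈ · (1 + C₁₆/C₁₈)        (≤ 0 in a labeled run)
    evolution(t) = v₁₆ − v₁₈ · C₁₆/C₁₈        (gross PSII production)
    net(t)       = evolution + uptake  =  v₁₆ + v₁₈   (exact identity)

¹⁶O¹⁸O (m/z 34) is neglected under the high-enrichment assumption; the
``enrichment`` output tracks the ¹⁸O₂ share of total O₂ so that runs where
the assumption erodes can be flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .errors import AnalysisError
from .series import FluxSeries

__all__ = ["IsotopeO2Result", "o2_exchange_rates", "isotopologue_pair_fraction"]


@dataclass
class IsotopeO2Result:
    """Gross uptake / gross evolution / net O₂ rates and running integrals."""

    time: np.ndarray
    uptake: np.ndarray  # µmol L⁻¹ s⁻¹, <= 0 by convention
    evolution: np.ndarray  # µmol L⁻¹ s⁻¹
    net: np.ndarray  # µmol L⁻¹ s⁻¹, = evolution + uptake exactly
    mask: np.ndarray  # True where rates are defined (C18 above threshold)
    enrichment: np.ndarray  # C18 / (C16 + C18)
    cumulative: dict[str, np.ndarray] = field(default_factory=dict)


def o2_exchange_rates(
    time: np.ndarray,
    C16: np.ndarray,
    C18: np.ndarray,
    v16: np.ndarray,
    v18: np.ndarray,
    *,
    min_label: float = 0.0,
    cumulate_from: float | None = None,
) -> IsotopeO2Result:
    """Partition net O₂ exchange into gross evolution and gross uptake.

    Inputs are concentration and consumption-corrected rate series for
    ¹⁶O₂ and ¹⁸O₂ on a common grid.  Points where ``C18 <= min_label`` are
    masked (no label, the partition is undefined) rather than extrapolated;
    an error is raised only when no point carries label at all.

    ``cumulate_from`` (seconds) additionally integrates the three rates
    from that origin (masked points contribute zero).
    """
    time = np.asarray(time, float)
    C16, C18 = np.asarray(C16, float), np.asarray(C18, float)
    v16, v18 = np.asarray(v16, float), np.asarray(v18, float)
    mask = C18 > max(min_label, 0.0)
    if not mask.any():
        raise AnalysisError("no label present: C18 non-positive over the whole series")

    ratio = np.full_like(C18, np.nan)
    np.divide(C16, C18, out=ratio, where=mask)
    uptake = np.where(mask, v18 * (1.0 + ratio), np.nan)
    evolution = np.where(mask, v16 - v18 * ratio, np.nan)
    net = evolution + uptake  # identical to v16 + v18 where defined
    total = C16 + C18
    enrichment = np.divide(
        C18, total, out=np.zeros_like(C18), where=total > 0
    )

    cumulative: dict[str, np.ndarray] = {}
    if cumulate_from is not None:
        for name, v in (("uptake", uptake), ("evolution", evolution), ("net", net)):
            vz = np.where(mask, v, 0.0)
            cum = integrate.cumulative_trapezoid(vz, time, initial=0.0)
            cum -= np.interp(cumulate_from, time, cum)
            cumulative[name] = cum
    return IsotopeO2Result(time, uptake, evolution, net, mask, enrichment, cumulative)


def o2_result_from_fluxes(
    conc16: np.ndarray,
    conc18: np.ndarray,
    flux: FluxSeries,
    name16: str = "O2",
    name18: str = "18O2",
    **kwargs,
) -> IsotopeO2Result:
    """Convenience wrapper taking a FluxSeries holding both isotopologues."""
    return o2_exchange_rates(
        flux.time, conc16, conc18, flux[name16], flux[name18], **kwargs
    )


def isotopologue_pair_fraction(atom_abundance: float) -> float:
    """Fraction of homonuclear pairs at a given atom abundance.

    Two atoms drawn independently: a ¹⁶O abundance of 0.998 gives
    0.998² ≈ 0.996 of the O₂ produced from water as ¹⁶O¹⁶O — the basis of
    the "water splitting produces unlabeled O₂" assumption.
    """
    if not (0.0 <= atom_abundance <= 1.0):
        raise ValueError(f"atom abundance must lie in [0, 1], got {atom_abundance}")
    return atom_abundance**2
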