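"""Gas and isotopologue registry: fragmentation patterns and solubility.

A :class:`GasRegistry` holds, per gas species, the electron-impact
fragmentation pattern (relative intensity per m/z channel, base peak = 100)
and a solubility table (equilibrium dissolved concentration in µmol L⁻¹
under 1 atm of the pure gas, tabulated against temperature).  The packaged
default registry covers the common MIMS analytes (H₂, D₂, H₂O, N₂, NO, O₂,
Ar, CO₂, N₂O) plus the isotopologues used by the isotope analyses
(¹⁸O₂ m/z 36, ¹⁶O¹⁸O m/z 34, HD m/z 3, ¹³CO₂ m/z 45, ¹³C¹⁸O¹⁶O m/z 47,
¹³C¹⁸O₂ m/z 49), each with a molecular-ion-only pattern.

Fragmentation patterns depend on the ion source; the packaged table is
typical reference data and can be replaced with an instrument-specific
config file of the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import RegistryValidationError, TemperatureRangeError

__all__ = [
    "GasSpecies",
    "GasRegistry",
    "load_gas_registry",
    "fragmentation_intensity",
    "equilibrium_concentration",
]


@dataclass(frozen=True)
class GasSpecies:
    """One gas (or isotopologue) and its registry data.

    Parameters
    ----------
    name:
        Registry identifier, e.g. ``"O2"`` or ``"18O2"``.
    formula:
        Human-readable formula.
    nominal_mz:
        m/z of the molecular ion (integer, unit resolution).
    fragmentation:
        Mapping m/z → relative intensity in percent of the base peak.
        Exactly one entry must equal 100.
    solubility_table:
        Sequence of ``(temperature_C, C_eq_umol_per_L)`` pairs at 1 atm of
        the pure gas, strictly decreasing in concentration with rising
        temperature.  ``None`` for species without solubility data (H₂O).
    isotopologue_of:
        Parent species name for isotopologues (they inherit the parent's
        solubility when their own table is absent).
    air_partial_pressure_atm:
        Mole fraction in dry air, used by air-equilibrium calibration.
    """

    name: str
    formula: str
    nominal_mz: int
    fragmentation: Mapping[int, float]
    solubility_table: tuple[tuple[float, float], ...] | None = None
    isotopologue_of: str | None = None
    air_partial_pressure_atm: float = 0.0

    def validate(self) -> None:
        if not self.fragmentation:
            raise RegistryValidationError(
                f"species {self.name!r}: fragmentation table is empty"
            )
        base_peaks = [mz for mz, v in self.fragmentation.items() if v == 100]
        if len(base_peaks) != 1:
            raise RegistryValidationError(
                f"species {self.name!r}: fragmentation must contain exactly one "
                f"base peak (intensity 100), found {len(base_peaks)}"
            )
        for mz, v in self.fragmentation.items():
            if not isinstance(mz, (int, np.integer)):
                raise RegistryValidationError(
                    f"species {self.name!r}: non-integer m/z {mz!r} in fragmentation"
                )
            if not isinstance(v, (int, float)) or isinstance(v, bool) or not np.isfinite(v):
                raise RegistryValidationError(
                    f"species {self.name!r}: non-numeric intensity at m/z {mz}"
                )
            if not (0 < v <= 100):
                raise RegistryValidationError(
                    f"species {self.name!r}: intensity at m/z {mz} must lie in "
                    f"(0, 100], got {v}"
                )
        if self.solubility_table is not None:
            tab = self.solubility_table
            if len(tab) < 2:
                raise RegistryValidationError(
                    f"species {self.name!r}: solubility table needs >= 2 rows"
                )
            temps = [t for t, _ in tab]
            concs = [c for _, c in tab]
            if any(c <= 0 for c in concs):
                raise RegistryValidationError(
                    f"species {self.name!r}: solubility must be strictly positive"
                )
            if any(t1 >= t2 for t1, t2 in zip(temps, temps[1:])):
                raise RegistryValidationError(
                    f"species {self.name!r}: solubility temperatures must increase"
                )
            if any(c1 <= c2 for c1, c2 in zip(concs, concs[1:])):
                raise RegistryValidationError(
                    f"species {self.name!r}: solubility must decrease with temperature"
                )

    @property
    def base_peak_mz(self) -> int:
        return next(mz for mz, v in self.fragmentation.items() if v == 100)


@dataclass
class GasRegistry:
    """Collection of :class:`GasSpecies`, keyed by name."""

    species: dict[str, GasSpecies] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.species

    def __getitem__(self, name: str) -> GasSpecies:
        try:
            return self.species[name]
        except KeyError:
            raise KeyError(
                f"unknown species {name!r}; registry has "
                f"{sorted(self.species)}"
            ) from None

    @property
    def channels(self) -> list[int]:
        """Sorted union of all m/z channels any species fragments into."""
        mzs: set[int] = set()
        for sp in self.species.values():
            mzs.update(int(m) for m in sp.fragmentation)
        return sorted(mzs)

    def solubility_for(self, name: str) -> tuple[tuple[float, float], ...]:
        """Solubility table for a species, resolving isotopologue parents."""
        sp = self[name]
        if sp.solubility_table is not None:
            return sp.solubility_table
        if sp.isotopologue_of is not None:
            parent = self[sp.isotopologue_of]
            if parent.solubility_table is not None:
                return parent.solubility_table
        raise RegistryValidationError(
            f"species {name!r} has no solubility table (and no parent with one)"
        )


class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys (duplicate species)."""


def _strict_mapping(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise RegistryValidationError(f"duplicate species/key {key!r} in config")
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_mapping
)


def _default_config_path() -> Path:
    return Path(str(resources.files("mimsflux").joinpath("data/gas_registry.yaml")))


def load_gas_registry(config_path: str | Path | None = None) -> GasRegistry:
    """Load a gas registry from a YAML config (packaged default when None).

    Raises
    ------
    RegistryValidationError
        On duplicate species names, absent base peaks, non-numeric
        intensities or non-monotone solubility, naming the species at fault.
    """
    path = Path(config_path) if config_path is not None else _default_config_path()
    with open(path) as fh:
        raw = yaml.load(fh, Loader=_StrictLoader)
    if not isinstance(raw, dict) or "species" not in raw:
        raise RegistryValidationError(f"{path}: config must have a 'species' block")

    reg = GasRegistry()
    for name, block in raw["species"].items():
        name = str(name)
        if name in reg.species:
            raise RegistryValidationError(f"duplicate species {name!r}")
        if block is None or "fragments" not in block:
            raise RegistryValidationError(f"species {name!r}: missing 'fragments'")
        sol = block.get("solubility")
        sp = GasSpecies(
            name=name,
            formula=str(block.get("formula", name)),
            nominal_mz=int(block["nominal_mz"]),
            fragmentation={int(k): v for k, v in block["fragments"].items()},
            solubility_table=(
                tuple((float(t), float(c)) for t, c in sol) if sol else None
            ),
            isotopologue_of=block.get("isotopologue_of"),
            air_partial_pressure_atm=float(block.get("air_partial_pressure_atm", 0.0)),
        )
        sp.validate()
        reg.species[name] = sp

    for sp in reg.species.values():
        if sp.isotopologue_of is not None and sp.isotopologue_of not in reg:
            raise RegistryValidationError(
                f"species {sp.name!r}: unknown parent {sp.isotopologue_of!r}"
            )
    return reg


def fragmentation_intensity(registry: GasRegistry, species: str, mz: int) -> float:
    """Tabulated relative intensity (percent of base peak) of `species` at `mz`.

    Returns 0.0 when the species has no line at that channel.  Pure lookup:
    repeated calls are identical.
    """
    sp = registry[species]
    return float(sp.fragmentation.get(int(mz), 0.0))


def equilibrium_concentration(
    species: GasSpecies,
    temperature: float,
    partial_pressure: float,
    *,
    registry: GasRegistry | None = None,
) -> float:
    """Equilibrium dissolved concentration (µmol L⁻¹) at a partial pressure.

    Henry behavior: linear in ``partial_pressure`` (atm); the 1-atm
    solubility is linearly interpolated in temperature within the tabulated
    range — no extrapolation.

    Parameters
    ----------
    registry:
        Optional; lets isotopologues inherit the parent solubility table.
    """
    if partial_pressure < 0:
        raise ValueError("partial_pressure must be >= 0")
    table = species.solubility_table
    if table is None and registry is not None:
        table = registry.solubility_for(species.name)
    if table is None:
        raise RegistryValidationError(
            f"species {species.name!r} has no solubility table"
        )
    temps = np.array([t for t, _ in table])
    concs = np.array([c for _, c in table])
    if not (temps[0] <= temperature <= temps[-1]):
        raise TemperatureRangeError(
            f"temperature {temperature} °C outside tabulated range "
            f"[{temps[0]}, {temps[-1]}] for {species.name!r}"
        )
    c1atm = float(np.interp(temperature, temps, concs))
    return c1atm * partial_pressure
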