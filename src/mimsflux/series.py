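"""Shared series containers: dissolved concentrations and exchange rates."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ConcentrationSeries", "FluxSeries"]


@dataclass
class ConcentrationSeries:
    """Per-species dissolved concentration (µmol L⁻¹) on a common time grid."""

    time: np.ndarray
    data: dict[str, np.ndarray]
    provenance: str = ""
    clipped_counts: dict[str, int] = field(default_factory=dict)
    flagged_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.data = {k: np.asarray(v, dtype=float) for k, v in self.data.items()}
        for name, arr in self.data.items():
            if arr.shape != self.time.shape:
                raise ValueError(f"species {name!r}: length mismatch with time")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"species {name!r}: non-finite concentration")

    @property
    def species(self) -> list[str]:
        return list(self.data)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    def window_mask(self, t0: float, t1: float) -> np.ndarray:
        return (self.time >= t0) & (self.time <= t1)

    def with_data(self, data: dict[str, np.ndarray]) -> "ConcentrationSeries":
        return replace(self, data=data)


@dataclass
class FluxSeries:
    """Signed biological exchange rates (µmol L⁻¹ s⁻¹) and running integrals.

    Sign convention: positive = release into the medium, negative = uptake.
    ``cumulative`` entries (µmol L⁻¹), when present, are trapezoidal running
    integrals of ``rate`` zeroed at the integration origin.
    """

    time: np.ndarray
    rate: dict[str, np.ndarray]
    cumulative: dict[str, np.ndarray] = field(default_factory=dict)
    smoothing_window: float = 0.0
    units: str = "umol/L/s"
    edge_flags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.rate = {k: np.asarray(v, dtype=float) for k, v in self.rate.items()}
        for name, arr in self.rate.items():
            if arr.shape != self.time.shape:
                raise ValueError(f"species {name!r}: length mismatch with time")

    @property
    def species(self) -> list[str]:
        return list(self.rate)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.rate[name]

    def window_mask(self, t0: float, t1: float) -> np.ndarray:
        return (self.time >= t0) & (self.time <= t1)
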