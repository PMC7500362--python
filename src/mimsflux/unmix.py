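"""Spectral unmixing of shared m/z channels.

Several analytes can contribute to one channel: CO₂ and N₂O share their
molecular ion at m/z 44, CO₂ fragments onto m/z 28 under N₂, and D₂ leaves
a small fragment (1.59 % of its base peak) on the H₂ channel at m/z 2.
With the registry's fragmentation patterns the observed channel vector is
a linear mixture ``S ≈ F·x`` of per-species base-peak-equivalent signals
``x ≥ 0``; nonnegative least squares resolves it channel-set permitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .errors import UnmixingError
from .registry import GasRegistry, fragmentation_intensity
from .trace import TraceSet

__all__ = [
    "MixingMatrix",
    "build_mixing_matrix",
    "unmix_channels",
    "correct_h2_channel",
]


@dataclass(frozen=True)
class MixingMatrix:
    """Fragmentation mixing matrix F[channel, species], base peak = 1."""

    channels: tuple[int, ...]
    species: tuple[str, ...]
    F: np.ndarray  # shape (len(channels), len(species)), entries in [0, 1]

    def column(self, species: str) -> np.ndarray:
        return self.F[:, self.species.index(species)]


def build_mixing_matrix(
    registry: GasRegistry,
    species: list[str],
    channels: list[int],
) -> MixingMatrix:
    """Assemble F[c, g] = fragmentation(g, c)/100 and check identifiability.

    Every species' base peak must be among the channels, and the matrix
    must have full column rank; otherwise the offending species (pair) is
    named in the error.
    """
    chans = tuple(int(c) for c in channels)
    specs = tuple(species)
    F = np.zeros((len(chans), len(specs)))
    for j, g in enumerate(specs):
        base = registry[g].base_peak_mz
        if base not in chans:
            raise UnmixingError(
                f"species {g!r}: base peak m/z {base} not among channels {chans}"
            )
        for i, c in enumerate(chans):
            F[i, j] = fragmentation_intensity(registry, g, c) / 100.0
    rank = np.linalg.matrix_rank(F)
    if rank < len(specs):
        # name a dependent pair for the user
        for a in range(len(specs)):
            for b in range(a + 1, len(specs)):
                sub = F[:, [a, b]]
                if np.linalg.matrix_rank(sub) < 2:
                    raise UnmixingError(
                        f"species {specs[a]!r} and {specs[b]!r} are "
                        f"indistinguishable on channels {chans}"
                    )
        raise UnmixingError(
            f"mixing matrix rank-deficient (rank {rank} < {len(specs)}) "
            f"on channels {chans}"
        )
    return MixingMatrix(chans, specs, F)


def unmix_channels(
    trace: TraceSet,
    M: MixingMatrix,
    *,
    residual_threshold: float | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Per-species base-peak-equivalent signals by nonnegative least squares.

    Baselines must already be subtracted from the trace.  Returns
    ``(signals, residual_norm, flagged)`` where ``signals[g]`` has the
    length of the trace, ``residual_norm[t]`` is the per-sample ‖S − F·x‖,
    and ``flagged`` marks samples whose residual exceeds
    ``residual_threshold`` (never flags when threshold is None).

    All-zero channel vectors yield zero output without error.
    """
    n = trace.time.size
    S = np.stack([trace.channel(c) for c in M.channels], axis=0)  # (nc, n)
    X = np.zeros((len(M.species), n))
    resid = np.zeros(n)
    for t in range(n):
        s = S[:, t]
        if not np.any(s):
            continue
        x, r = nnls(M.F, s)
        X[:, t] = x
        resid[t] = r
    flagged = (
        resid > residual_threshold
        if residual_threshold is not None
        else np.zeros(n, dtype=bool)
    )
    signals = {g: X[j] for j, g in enumerate(M.species)}
    return signals, resid, flagged


def correct_h2_channel(trace: TraceSet, registry: GasRegistry) -> TraceSet:
    """Remove D₂'s fragment contribution from the H₂ channel (m/z 2).

    D₂ produces a line at m/z 2 at 1.59 % of its base peak (m/z 4); the
    corrected H₂ channel is ``mz2 − 0.0159·mz4``.  Requires both channels.
    """
    frac = fragmentation_intensity(registry, "D2", 2) / 100.0
    mz2 = trace.channel(2)
    mz4 = trace.channel(4)
    channels = dict(trace.channels)
    channels[2] = mz2 - frac * mz4
    return trace.with_channels(channels)
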