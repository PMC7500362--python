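"""Raw MIMS traces: time × m/z ion currents, metadata and event markers.

The on-disk dialect is deliberately plain: a CSV with a ``time`` column
(seconds from trace start) and one column per observed channel named
``mz<k>`` (integer m/z, unit resolution), currents in amperes.  Experiment
metadata travels in a YAML sidecar ``<stem>.meta.yaml`` and event markers
(injections, light-on, vessel-closed) in ``<stem>.events.csv`` with columns
``time,label``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import TraceParseError

__all__ = ["Event", "TraceMeta", "TraceSet", "read_trace", "write_trace"]

_MZ_COL = re.compile(r"^mz(\d+)$")


@dataclass(frozen=True)
class Event:
    """A timestamped protocol marker, e.g. ``Event(300.0, "light_on")``."""

    time: float
    label: str


@dataclass(frozen=True)
class TraceMeta:
    """Experiment metadata attached to a trace."""

    temperature_C: float = 25.0
    vessel_volume_mL: float = 1.5
    pH: float = 7.2
    chlorophyll_ug_per_mL: float | None = None


@dataclass
class TraceSet:
    """A multi-channel ion-current time series.

    Attributes
    ----------
    time:
        Seconds from trace start, strictly increasing.
    channels:
        Mapping m/z → ion current (amperes), one array per channel, all the
        length of ``time``.
    meta, events:
        Experiment metadata and protocol markers (absolute trace time).
    """

    time: np.ndarray
    channels: dict[int, np.ndarray]
    meta: TraceMeta = field(default_factory=TraceMeta)
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 1:
            raise TraceParseError("time must be a non-empty 1-D array")
        dt = np.diff(self.time)
        if dt.size and not np.all(dt > 0):
            i = int(np.argmax(dt <= 0))
            raise TraceParseError(
                f"time not strictly increasing at row {i + 1} "
                f"(t={self.time[i + 1]} after t={self.time[i]})"
            )
        clean = {}
        for mz, s in self.channels.items():
            arr = np.asarray(s, dtype=float)
            if arr.shape != self.time.shape:
                raise TraceParseError(
                    f"channel mz{mz}: length {arr.size} != time length {self.time.size}"
                )
            if not np.all(np.isfinite(arr)):
                raise TraceParseError(f"channel mz{mz}: non-finite current")
            clean[int(mz)] = arr
        self.channels = clean

    @property
    def mz_list(self) -> list[int]:
        return sorted(self.channels)

    def channel(self, mz: int) -> np.ndarray:
        try:
            return self.channels[int(mz)]
        except KeyError:
            raise KeyError(
                f"trace has no channel mz{mz}; available: {self.mz_list}"
            ) from None

    def window_mask(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask for samples with t0 <= time <= t1."""
        return (self.time >= t0) & (self.time <= t1)

    def event_time(self, label: str) -> float:
        """Time of the first event whose label matches exactly."""
        for ev in self.events:
            if ev.label == label:
                return ev.time
        raise KeyError(f"no event labeled {label!r}; events: "
                       f"{[e.label for e in self.events]}")

    def with_channels(self, channels: dict[int, np.ndarray]) -> "TraceSet":
        return replace(self, channels=channels)


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".meta.yaml"), stem.with_suffix(".events.csv")


def read_trace(path: str | Path) -> TraceSet:
    """Read a trace CSV plus optional sidecars into a :class:`TraceSet`.

    Raises :class:`TraceParseError` with a line number for a missing time
    column, non-monotone time, or ragged rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except pd.errors.ParserError as exc:  # ragged rows carry a line number
        raise TraceParseError(f"{path}: {exc}") from exc
    if "time" not in df.columns:
        raise TraceParseError(f"{path}: line 1: missing 'time' column")
    channels = {}
    for col in df.columns:
        m = _MZ_COL.match(col)
        if m:
            channels[int(m.group(1))] = df[col].to_numpy(dtype=float)
        elif col != "time":
            raise TraceParseError(f"{path}: line 1: unrecognized column {col!r}")
    if df[list(df.columns)].isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise TraceParseError(f"{path}: line {row + 2}: ragged/missing value")

    meta_path, events_path = _sidecar_paths(path)
    meta = TraceMeta()
    if meta_path.exists():
        with open(meta_path) as fh:
            raw = yaml.safe_load(fh) or {}
        meta = TraceMeta(
            temperature_C=float(raw.get("temperature_C", 25.0)),
            vessel_volume_mL=float(raw.get("vessel_volume_mL", 1.5)),
            pH=float(raw.get("pH", 7.2)),
            chlorophyll_ug_per_mL=(
                float(raw["chlorophyll_ug_per_mL"])
                if raw.get("chlorophyll_ug_per_mL") is not None
                else None
            ),
        )
    events: list[Event] = []
    if events_path.exists():
        edf = pd.read_csv(events_path)
        events = [Event(float(t), str(lbl)) for t, lbl in zip(edf["time"], edf["label"])]

    try:
        return TraceSet(df["time"].to_numpy(dtype=float), channels, meta, events)
    except TraceParseError as exc:
        raise TraceParseError(f"{path}: {exc}") from exc


def write_trace(trace: TraceSet, path: str | Path) -> Path:
    """Write a trace (and sidecars) so that ``read_trace`` round-trips it."""
    path = Path(path)
    df = pd.DataFrame({"time": trace.time})
    for mz in trace.mz_list:
        df[f"mz{mz}"] = trace.channels[mz]
    df.to_csv(path, index=False, float_format="%.12g")

    meta_path, events_path = _sidecar_paths(path)
    meta = {
        "temperature_C": trace.meta.temperature_C,
        "vessel_volume_mL": trace.meta.vessel_volume_mL,
        "pH": trace.meta.pH,
    }
    if trace.meta.chlorophyll_ug_per_mL is not None:
        meta["chlorophyll_ug_per_mL"] = trace.meta.chlorophyll_ug_per_mL
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    if trace.events:
        pd.DataFrame(
            {"time": [e.time for e in trace.events],
             "label": [e.label for e in trace.events]}
        ).to_csv(events_path, index=False)
    return path


def isclose_trace(a: TraceSet, b: TraceSet, rtol: float = 1e-9) -> bool:
    """Numeric equality of two traces within float round-trip tolerance."""
    if a.mz_list != b.mz_list or a.time.size != b.time.size:
        return False
    if not np.allclose(a.time, b.time, rtol=rtol, atol=0):
        return False
    return all(
        np.allclose(a.channels[mz], b.channels[mz], rtol=rtol,
                    atol=rtol * max(1e-30, float(np.abs(a.channels[mz]).max())))
        for mz in a.mz_list
    ) and math.isclose(a.meta.temperature_C, b.meta.temperature_C)
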