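"""Shared data containers for the dCA analysis pipeline.

All times are seconds on a single recording clock whose origin is the start
of the recording.  ABP is in mmHg, NIRS haemoglobin signals in µM·mm
(pathlength-scaled concentration change), vitals in their clinical units
(HR beats/min, SpO2 %, ETCO2 kPa, mean ABP mmHg).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEMISPHERES = ("ischaemic", "contralateral")
#: channel roles by source-detector separation: 35 mm probes cortex, 10 mm scalp
ROLE_BY_SEPARATION = {35.0: "long", 10.0: "short"}


@dataclass(frozen=True)
class ChannelMeta:
    """Identity of one NIRS channel on the montage."""

    hemisphere: str
    separation_mm: float
    role: str  # "long" (cerebral) or "short" (extracerebral)
    territory_label: str = ""

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        expected = ROLE_BY_SEPARATION.get(float(self.separation_mm))
        if expected is not None and expected != self.role:
            raise ValueError(
                f"role {self.role!r} inconsistent with separation "
                f"{self.separation_mm} mm (expected {expected!r})"
            )
        if self.role not in ("long", "short"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class NirsChannel:
    """One NIRS channel: metadata plus its OxyHb trace at the raw rate."""

    name: str
    meta: ChannelMeta
    oxyhb: np.ndarray  # µM·mm, sampled at RawRecording.fs_raw


@dataclass
class Event:
    name: str
    time_s: float


@dataclass
class GroundTruth:
    """Generator-side truth attached to synthetic recordings for testing."""

    beat_times: np.ndarray
    artifact_masks: dict[str, np.ndarray] = field(default_factory=dict)
    scalp: np.ndarray | None = None
    config: object | None = None


@dataclass
class RawRecording:
    """Synchronized multichannel recording on one clock.

    ``abp`` and every channel's ``oxyhb`` are sampled at ``fs_raw``;
    ``vitals`` is a DataFrame with a ``time_s`` column plus one column per
    monitored vital, sampled at ``vitals_fs``.
    """

    subject_id: str
    fs_raw: float
    abp: np.ndarray
    channels: list[NirsChannel]
    vitals: pd.DataFrame
    vitals_fs: float
    events: list[Event]
    truth: GroundTruth | None = None

    @property
    def duration_s(self) -> float:
        return len(self.abp) / self.fs_raw

    def event_time(self, name: str) -> float | None:
        for ev in self.events:
            if ev.name == name:
                return ev.time_s
        return None

    def event_times(self, name: str) -> list[float]:
        return [ev.time_s for ev in self.events if ev.name == name]


@dataclass
class BeatSeries:
    """Beat onsets (s) and per-beat means of one signal over inter-onset
    intervals; ``beat_means[i]`` covers ``[beat_onsets[i], beat_onsets[i+1])``.
    """

    beat_onsets: np.ndarray
    beat_means: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.beat_onsets) <= 0):
            raise ValueError("beat onsets must be strictly increasing")
        if len(self.beat_means) != len(self.beat_onsets) - 1:
            raise ValueError("expected one mean per inter-onset interval")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.beat_onsets[:-1] + self.beat_onsets[1:])


@dataclass
class UniformSeries:
    """Uniformly sampled series (the 10 Hz beat-averaged representation)."""

    start_time: float
    fs: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("UniformSeries must be finite")

    @property
    def time(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.fs

    @property
    def end_time(self) -> float:
        return self.start_time + (len(self.values) - 1) / self.fs

    def slice(self, start_s: float, end_s: float) -> "UniformSeries":
        """Samples with start_s <= t <= end_s (inclusive of both edges)."""
        i0 = int(np.ceil((start_s - self.start_time) * self.fs - 1e-9))
        i1 = int(np.floor((end_s - self.start_time) * self.fs + 1e-9))
        i0 = max(i0, 0)
        if i1 < i0:
            raise ValueError("empty slice")
        return UniformSeries(
            start_time=self.start_time + i0 / self.fs,
            fs=self.fs,
            values=self.values[i0 : i1 + 1],
        )
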