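"""Core containers shared by every pipeline stage.

A :class:`Recording` is a channels-by-samples matrix in microvolts together
with its sampling rate, channel labels and a provenance log.  Every stage of
the pipeline consumes and returns Recordings, appending a short annotation to
``history`` so the final cleaning report can reconstruct what happened.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

__all__ = [
    "Recording",
    "MiniGame",
    "SessionMeta",
    "SessionExcluded",
    "CleaningReport",
]


class SessionExcluded(Exception):
    """Raised (or carried as a status) when a session cannot continue.

    Mirrors the pipeline's exclusion events: too few clean channels, all
    windows rejected, no converged decomposition, or no brain IC retained.
    """

    def __init__(self, stage: str, reason: str):
        self.stage = stage
        self.reason = reason
        super().__init__(f"session excluded at {stage}: {reason}")


@dataclass
class Recording:
    """Multichannel EEG segment in µV.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz (125 Hz for the 16-channel Cyton+Daisy setup).
    channel_labels : list of str
        Unique channel names, one per row of ``data``.
    start_time : int
        Absolute timestamp of the first sample, milliseconds since epoch.
    channel_locations : dict or None
        Optional montage entries keyed by label.
    history : list of str
        Ordered stage annotations (provenance log).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    start_time: int = 0
    channel_locations: dict[str, Any] | None = None
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def log(self, message: str) -> None:
        self.history.append(message)

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            start_time=self.start_time,
            channel_locations=dict(self.channel_locations)
            if self.channel_locations
            else None,
            history=list(self.history),
        )

    def with_data(self, data: np.ndarray, note: str | None = None) -> "Recording":
        """Return a copy carrying new sample data (same channels)."""
        out = self.copy()
        out.data = np.asarray(data, dtype=np.float64)
        if out.data.shape[0] != len(out.channel_labels):
            raise ValueError("with_data must preserve the channel count")
        if note:
            out.log(note)
        return out

    def select_channels(self, keep: list[str], note: str | None = None) -> "Recording":
        idx = [self.channel_labels.index(lbl) for lbl in keep]
        out = Recording(
            data=self.data[idx].copy(),
            fs=self.fs,
            channel_labels=list(keep),
            start_time=self.start_time,
            channel_locations={k: self.channel_locations[k] for k in keep if k in self.channel_locations}
            if self.channel_locations
            else None,
            history=list(self.history),
        )
        if note:
            out.log(note)
        return out

    def slice_samples(self, start: int, stop: int, note: str | None = None) -> "Recording":
        """Half-open sample slice [start, stop) with start_time updated."""
        start = max(0, start)
        stop = min(self.n_samples, stop)
        out = self.copy()
        out.data = self.data[:, start:stop].copy()
        out.start_time = int(self.start_time + round(start / self.fs * 1000.0))
        if note:
            out.log(note)
        return out


@dataclass
class MiniGame:
    """One mini-game interval inside a gameplay session."""

    label: str
    index: int
    start: int  # ms since epoch
    end: int  # ms since epoch
    adjustment_s: float = 0.0

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("mini-game index starts at 1")
        if self.start >= self.end:
            raise ValueError("mini-game start must precede end")


@dataclass
class SessionMeta:
    """Session metadata driving trimming and segmentation.

    ``condition`` is GT (still baseline) or MVMT (full-body movement);
    timestamps are milliseconds since epoch, ``buffer_s`` pads the gameplay
    interval on both sides.
    """

    participant_id: str
    condition: str
    gameplay_start: int
    gameplay_end: int
    buffer_s: float = 2.0
    minigames: list[MiniGame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.condition not in ("GT", "MVMT"):
            raise ValueError("condition must be 'GT' or 'MVMT'")
        if self.gameplay_start >= self.gameplay_end:
            raise ValueError("gameplay_start must precede gameplay_end")
        if self.buffer_s < 0:
            raise ValueError("buffer_s must be non-negative")
        lo = self.gameplay_start - self.buffer_s * 1000.0
        hi = self.gameplay_end + self.buffer_s * 1000.0
        for mg in self.minigames:
            if mg.start < lo or mg.end > hi:
                raise ValueError(
                    f"mini-game {mg.label}_{mg.index} outside buffered gameplay interval"
                )

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SessionMeta":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        payload["minigames"] = [MiniGame(**mg) for mg in payload.get("minigames", [])]
        return cls(**payload)


@dataclass
class CleaningReport:
    """Structured per-stage log assembled by the end-to-end pipeline."""

    session_id: str = ""
    condition: str = ""
    status: str = "ok"  # "ok" | "excluded"
    excluded_reason: str = ""
    channels_total: int = 0
    channels_removed: list[dict[str, Any]] = field(default_factory=list)
    channel_retention: float = float("nan")
    clean_reference_fraction: float = float("nan")
    reconstructed_fraction: float = float("nan")
    dropped_windows_s: float = 0.0
    filter_cutoff_hz: float = float("nan")
    n_ics: int = 0
    n_retained_ics: int = 0
    ic_decisions: list[dict[str, Any]] = field(default_factory=list)
    history: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CleaningReport":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))
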