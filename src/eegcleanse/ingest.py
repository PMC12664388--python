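"""Raw-signal ingestion and segmentation.

Parses OpenBCI-GUI-style text recordings ('%'-prefixed header lines followed
by comma-separated sample rows), converts them to a standardized CSV layout,
synchronizes recordings with gameplay timestamps, and cuts them into
per-mini-game segments grouped by condition and participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import Recording, SessionMeta

__all__ = [
    "OpenBCIDialect",
    "IngestionError",
    "SynchronizationError",
    "parse_openbci_txt",
    "write_csv",
    "read_csv",
    "trim_to_gameplay",
    "segment_minigames",
]


class IngestionError(ValueError):
    pass


class SynchronizationError(ValueError):
    pass


@dataclass
class OpenBCIDialect:
    """Parser configuration for the OpenBCI GUI text format.

    Defaults match a Cyton+Daisy export: sample index first, 16 EXG channels,
    auxiliary columns, and a 'Timestamp' column in milliseconds.  Column
    positions are resolved from the column-name row when one is present;
    otherwise the index fields below are used.
    """

    comment_prefix: str = "%"
    eeg_col_start: int = 1
    n_eeg: int = 16
    timestamp_col: int = -1
    channel_labels: list[str] = field(default_factory=list)

    def labels(self) -> list[str]:
        if self.channel_labels:
            return list(self.channel_labels)
        return [f"EXG{i}" for i in range(self.n_eeg)]


def _resolve_columns(header_fields: list[str], dialect: OpenBCIDialect):
    """Locate EEG and timestamp columns from a column-name row."""
    lowered = [f.strip().lower() for f in header_fields]
    ts_candidates = [
        i for i, f in enumerate(lowered)
        if "timestamp" in f and "formatted" not in f
    ]
    if not ts_candidates:
        raise IngestionError(
            "no 'Timestamp' column found in the recording header row"
        )
    eeg_cols = [i for i, f in enumerate(lowered) if "exg channel" in f]
    if not eeg_cols:
        eeg_cols = list(
            range(dialect.eeg_col_start, dialect.eeg_col_start + dialect.n_eeg)
        )
        labels = dialect.labels()
    else:
        labels = [header_fields[i].strip() for i in eeg_cols]
    return eeg_cols, ts_candidates[0], labels


def parse_openbci_txt(path, dialect: OpenBCIDialect | None = None) -> Recording:
    """Parse a raw OpenBCI text export into a :class:`Recording`.

    Header lines are prefixed with the comment marker; the sampling rate is
    read from a ``Sample Rate = <x> Hz`` header line when present (default
    125).  Only EEG channels are retained, in file order, µV preserved.
    Malformed rows are dropped and counted in the history, never interpolated.
    """
    dialect = dialect or OpenBCIDialect()
    fs = 125.0
    rows: list[list[float]] = []
    timestamps: list[float] = []
    n_dropped = 0
    eeg_cols: list[int] | None = None
    ts_col: int | None = None
    labels = dialect.labels()

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(dialect.comment_prefix):
                low = line.lower()
                if "sample rate" in low and "=" in line:
                    try:
                        fs = float(low.split("=")[1].split("hz")[0].strip())
                    except ValueError:
                        pass
                continue
            fields = line.split(",")
            if eeg_cols is None:
                # the first non-numeric row is the column-name header
                try:
                    float(fields[0])
                except ValueError:
                    eeg_cols, ts_col, labels = _resolve_columns(fields, dialect)
                    continue
                eeg_cols = list(
                    range(dialect.eeg_col_start, dialect.eeg_col_start + dialect.n_eeg)
                )
                ts_col = dialect.timestamp_col
            try:
                vals = [float(fields[c]) for c in eeg_cols]
                ts = float(fields[ts_col])
            except (ValueError, IndexError):
                n_dropped += 1
                continue
            rows.append(vals)
            timestamps.append(ts)

    if not rows:
        raise IngestionError(f"no valid data rows in {path}")

    rec = Recording(
        data=np.asarray(rows, dtype=np.float64).T,
        fs=fs,
        channel_labels=labels,
        start_time=int(round(timestamps[0])),
    )
    rec.log(
        f"ingest: parsed {rec.n_samples} samples x {rec.n_channels} channels "
        f"at {fs:g} Hz; dropped {n_dropped} malformed rows"
    )
    return rec


def write_csv(rec: Recording, path) -> None:
    """Write a Recording as standardized CSV: channel columns + timestamp.

    One header row, one row per sample; timestamps in ms reconstructed from
    ``start_time`` and the sample index (per-row logger timestamps jitter, so
    the nominal clock is authoritative).
    """
    ts = rec.start_time + np.arange(rec.n_samples) / rec.fs * 1000.0
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    df["timestamp"] = ts
    df.to_csv(path, index=False, float_format="%.6f")


def read_csv(path) -> Recording:
    """Read a CSV written by :func:`write_csv`; fs inferred from timestamps."""
    df = pd.read_csv(path)
    if "timestamp" not in df.columns:
        raise IngestionError("CSV is missing the 'timestamp' column")
    ts = df["timestamp"].to_numpy(dtype=np.float64)
    labels = [c for c in df.columns if c != "timestamp"]
    if len(ts) > 1:
        dt_ms = float(np.median(np.diff(ts)))
        fs = 1000.0 / dt_ms
    else:
        fs = 125.0
    rec = Recording(
        data=df[labels].to_numpy(dtype=np.float64).T,
        fs=fs,
        channel_labels=labels,
        start_time=int(round(ts[0])),
    )
    rec.log(f"ingest: read {rec.n_samples} samples from CSV")
    return rec


def trim_to_gameplay(rec: Recording, meta: SessionMeta) -> Recording:
    """Trim a recording to the buffered gameplay interval.

    The kept interval is ``[gameplay_start - buffer_s, gameplay_end +
    buffer_s)`` intersected with the available samples; times are converted to
    seconds relative to the recording start, half-open, 0-based samples.
    """
    t0 = (meta.gameplay_start - rec.start_time) / 1000.0 - meta.buffer_s
    t1 = (meta.gameplay_end - rec.start_time) / 1000.0 + meta.buffer_s
    if t1 <= 0 or t0 >= rec.duration_s:
        raise SynchronizationError(
            f"gameplay interval [{t0:.3f}, {t1:.3f}) s does not overlap "
            f"recording [0, {rec.duration_s:.3f}) s"
        )
    clipped = t0 < 0 or t1 > rec.duration_s
    start = max(0, int(np.floor(t0 * rec.fs)))
    stop = min(rec.n_samples, int(np.floor(t1 * rec.fs)))
    out = rec.slice_samples(start, stop)
    trimmed_head = start / rec.fs
    trimmed_tail = rec.duration_s - stop / rec.fs
    out.log(
        f"trim: kept [{start / rec.fs:.3f}, {stop / rec.fs:.3f}) s "
        f"(buffer {meta.buffer_s:g} s); trimmed {trimmed_head:.3f} s head, "
        f"{trimmed_tail:.3f} s tail"
        + ("; gameplay interval clipped to recording extent" if clipped else "")
    )
    return out


def segment_minigames(
    rec: Recording, meta: SessionMeta
) -> list[tuple[str, Recording]]:
    """Cut a trimmed recording into one segment per mini-game.

    Each segment is shifted by its ``adjustment_s`` and named
    ``{condition}/{participant}/{label}_{index}``.  Intervals fully outside
    the recording are skipped with a logged warning; overlapping intervals are
    emitted independently.
    """
    segments: list[tuple[str, Recording]] = []
    for mg in meta.minigames:
        t0 = (mg.start - rec.start_time) / 1000.0 + mg.adjustment_s
        t1 = (mg.end - rec.start_time) / 1000.0 + mg.adjustment_s
        name = f"{meta.condition}/{meta.participant_id}/{mg.label}_{mg.index}"
        if t1 <= 0 or t0 >= rec.duration_s:
            rec.log(f"segment: {name} outside recording, skipped")
            continue
        start = max(0, int(np.floor(t0 * rec.fs)))
        stop = min(rec.n_samples, int(np.floor(t1 * rec.fs)))
        seg = rec.slice_samples(start, stop)
        seg.log(
            f"segment: {name} [{start / rec.fs:.3f}, {stop / rec.fs:.3f}) s "
            f"(adjustment {mg.adjustment_s:+g} s)"
        )
        segments.append((name, seg))
    return segments
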