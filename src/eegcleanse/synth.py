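"""Synthetic EEG sessions with known ground truth.

Generates 16-channel, 125 Hz recordings that emulate the study conditions:
brain-like sources (amplitude-modulated alpha and beta oscillations, pink
noise) projected through a spatially smeared mixing matrix — neighbouring
scalp channels are highly correlated, as volume conduction makes real ones —
plus small independent sensor noise, with artifacts planted on top:

- ``impedance_channel``   — large constant offset (poor electrode contact);
- ``flatline_channel``    — a digitally constant channel (or stretch);
- ``uncorrelated_channel``— a channel replaced by independent noise;
- ``noisy_channel``       — a channel with grossly outlying amplitude;
- ``burst``               — transient high-amplitude noise on a channel
  subset (motion artifact);
- ``blink``               — low-passed positive pulses on frontal channels;
- ``line_noise``          — mains sinusoid across all channels.

Every artifact leaves a ground-truth mask, and the observed data equals the
clean data plus the summed artifact contributions exactly, so each cleaning
stage can be scored against what was planted.  Generation is fully
deterministic given the seed; the GT (still baseline) and MVMT (full-body
movement) presets share the same clean sources for a given seed so the two
conditions can be compared pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .recording import MiniGame, Recording, SessionMeta

__all__ = [
    "SourceSpec",
    "ArtifactSpec",
    "SynthSpec",
    "GroundTruth",
    "generate_session",
    "gt_profile",
    "mvmt_profile",
    "write_openbci_txt",
]

SOURCE_KINDS = ("alpha_osc", "beta_osc", "pink_noise")
CHANNEL_ARTIFACTS = (
    "impedance_channel",
    "flatline_channel",
    "uncorrelated_channel",
    "noisy_channel",
)
ARTIFACT_KINDS = CHANNEL_ARTIFACTS + ("burst", "line_noise", "blink")

EPOCH_MS = 1_700_000_000_000  # arbitrary absolute session start


@dataclass
class SourceSpec:
    kind: str
    amplitude: float  # µV RMS contribution scale

    def __post_init__(self) -> None:
        if self.kind not in SOURCE_KINDS:
            raise ValueError(f"unknown source kind {self.kind!r}")


@dataclass
class ArtifactSpec:
    kind: str
    channels: list[int] | None = None
    intervals: list[tuple[float, float]] | None = None  # seconds
    amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")


@dataclass
class SynthSpec:
    """Recipe for one synthetic session."""

    seed: int
    n_channels: int = 16
    fs: float = 125.0
    duration_s: float = 60.0
    condition: str = "GT"
    participant_id: str = "P01"
    sources: list[SourceSpec] = field(
        default_factory=lambda: [
            SourceSpec("alpha_osc", 20.0),
            SourceSpec("alpha_osc", 15.0),
            SourceSpec("beta_osc", 10.0),
            SourceSpec("pink_noise", 15.0),
        ]
    )
    artifacts: list[ArtifactSpec] = field(default_factory=list)
    sensor_noise_uv: float = 2.0
    line_freq: float = 50.0

    def __post_init__(self) -> None:
        for art in self.artifacts:
            for lo, hi in art.intervals or []:
                if not (0 <= lo < hi <= self.duration_s):
                    raise ValueError(
                        f"artifact interval [{lo}, {hi}) outside [0, {self.duration_s})"
                    )
        taken: dict[int, str] = {}
        for art in self.artifacts:
            if art.kind in CHANNEL_ARTIFACTS:
                for ch in art.channels or []:
                    if ch in taken:
                        raise ValueError(
                            f"conflicting artifact placement on channel {ch}: "
                            f"{taken[ch]} and {art.kind}"
                        )
                    taken[ch] = art.kind


@dataclass
class GroundTruth:
    clean_data: np.ndarray  # (k, n): brain mixture + sensor noise, no artifacts
    mixing: np.ndarray  # (k, n_sources)
    sources: np.ndarray  # (n_sources, n)
    artifact_masks: dict[str, np.ndarray]  # per-sample or per-channel booleans


def _make_sources(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    rows = []
    for src in spec.sources:
        if src.kind in ("alpha_osc", "beta_osc"):
            f0 = 10.0 if src.kind == "alpha_osc" else 20.0
            f0 += rng.uniform(-0.5, 0.5)
            phase = rng.uniform(0, 2 * np.pi)
            mod = 0.6 + 0.4 * np.sin(2 * np.pi * rng.uniform(0.1, 0.3) * t + rng.uniform(0, 2 * np.pi))
            x = mod * np.sin(2 * np.pi * f0 * t + phase)
        else:  # pink_noise via 1/f spectral shaping
            white = rng.standard_normal(n)
            spec_f = np.fft.rfft(white)
            freqs = np.fft.rfftfreq(n, 1 / spec.fs)
            shaping = 1.0 / np.sqrt(np.maximum(freqs, freqs[1]))
            x = np.fft.irfft(spec_f * shaping, n)
        x = x / x.std()
        rows.append(src.amplitude * x)
    return np.vstack(rows)


def _make_mixing(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Spatially smeared mixing: similar rows (volume conduction) with the
    condition number clipped to ≤ 10 so source recovery stays well-posed."""
    k, m = spec.n_channels, len(spec.sources)
    common = rng.uniform(0.5, 0.7, size=m)
    mix = np.tile(common, (k, 1)) + 0.1 * rng.standard_normal((k, m))
    # per-channel gains: electrode-to-source distance varies; widens the
    # amplitude spread without touching inter-channel correlation.  Evenly
    # spaced (then shuffled) so the spread never collapses by chance and a
    # planted amplitude outlier stays unambiguous under a robust z-score.
    gains = np.linspace(0.7, 1.4, k)
    rng.shuffle(gains)
    mix *= gains[:, None]
    u, s, vt = np.linalg.svd(mix, full_matrices=False)
    s = np.maximum(s, s[0] / 10.0)
    return u @ np.diag(s) @ vt


def _interval_mask(n: int, fs: float, intervals) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for lo, hi in intervals:
        mask[int(round(lo * fs)) : int(round(hi * fs))] = True
    return mask


def generate_session(spec: SynthSpec) -> tuple[Recording, SessionMeta, GroundTruth]:
    """Build one session: recording, metadata, and ground truth.

    Clean sources depend only on the seed (not on the artifact list), so GT
    and MVMT variants of the same seed share identical underlying brain
    activity.
    """
    ss = np.random.SeedSequence(spec.seed)
    clean_ss, art_ss = ss.spawn(2)
    rng_clean = np.random.default_rng(clean_ss)
    rng_art = np.random.default_rng(art_ss)

    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    sources = _make_sources(spec, rng_clean)
    mixing = _make_mixing(spec, rng_clean)
    clean = mixing @ sources
    clean += spec.sensor_noise_uv * rng_clean.standard_normal(clean.shape)

    data = clean.copy()
    masks: dict[str, np.ndarray] = {}
    k = spec.n_channels

    def channel_mask(kind: str) -> np.ndarray:
        return masks.setdefault(kind, np.zeros(k, dtype=bool))

    for art in spec.artifacts:
        if art.kind == "impedance_channel":
            offset = art.amplitude or 96_000.0
            for ch in art.channels or []:
                data[ch] += offset
                channel_mask(art.kind)[ch] = True
        elif art.kind == "flatline_channel":
            for ch in art.channels or []:
                if art.intervals:
                    m = _interval_mask(n, spec.fs, art.intervals)
                    data[ch, m] = data[ch, m][0] if m.any() else 0.0
                else:
                    data[ch, :] = 0.0
                channel_mask(art.kind)[ch] = True
        elif art.kind == "uncorrelated_channel":
            amp = art.amplitude or 20.0
            for ch in art.channels or []:
                data[ch] = amp * rng_art.standard_normal(n)
                channel_mask(art.kind)[ch] = True
        elif art.kind == "noisy_channel":
            gain = art.amplitude or 100.0
            for ch in art.channels or []:
                data[ch] = gain * data[ch]
                channel_mask(art.kind)[ch] = True
        elif art.kind == "burst":
            amp = art.amplitude or 400.0  # ~20x a 20 µV background
            chans = art.channels if art.channels is not None else list(range(k))
            m = _interval_mask(n, spec.fs, art.intervals or [])
            burst = np.zeros((k, n))
            burst[np.ix_(chans, np.where(m)[0])] = amp * rng_art.standard_normal(
                (len(chans), int(m.sum()))
            )
            data += burst
            masks["burst"] = masks.get("burst", np.zeros(n, dtype=bool)) | m
        elif art.kind == "line_noise":
            amp = art.amplitude or 5.0
            phase = rng_art.uniform(0, 2 * np.pi)
            data += amp * np.sin(2 * np.pi * spec.line_freq * t + phase)[None, :]
            masks["line_noise"] = np.ones(n, dtype=bool)
        elif art.kind == "blink":
            amp = art.amplitude or 150.0
            pulse_times = np.arange(1.0, spec.duration_s - 1.0, 4.0)
            m = np.zeros(n, dtype=bool)
            blink = np.zeros(n)
            for pt in pulse_times:
                i0 = int(round(pt * spec.fs))
                width = int(round(0.3 * spec.fs))
                blink[i0 : i0 + width] += np.hanning(width)
                m[i0 : i0 + width] = True
            b, a = butter(2, 8.0, fs=spec.fs)
            blink = filtfilt(b, a, blink) * amp
            frontal = art.channels or [0, 1]
            for ch in frontal:
                data[ch] += blink
            masks["blink"] = m

    # metadata: gameplay covers the interior, two mini-games split it
    margin_ms = int(min(4.0, spec.duration_s / 4) * 1000)
    g0 = EPOCH_MS + margin_ms
    g1 = EPOCH_MS + int(spec.duration_s * 1000) - margin_ms
    mid = (g0 + g1) // 2
    meta = SessionMeta(
        participant_id=spec.participant_id,
        condition=spec.condition,
        gameplay_start=g0,
        gameplay_end=g1,
        buffer_s=2.0,
        minigames=[
            MiniGame(label="memory", index=1, start=g0, end=mid),
            MiniGame(label="attention", index=2, start=mid, end=g1),
        ],
    )
    rec = Recording(
        data=data,
        fs=spec.fs,
        channel_labels=[f"EXG{i}" for i in range(k)],
        start_time=EPOCH_MS,
    )
    rec.log(
        f"synth: session seed={spec.seed} condition={spec.condition} "
        f"{spec.duration_s:g}s, {len(spec.artifacts)} artifact specs"
    )
    return rec, meta, GroundTruth(
        clean_data=clean, mixing=mixing, sources=sources, artifact_masks=masks
    )


def gt_profile(base: SynthSpec) -> SynthSpec:
    """Still-baseline preset: minimal artifact load (no bursts, no blinks)."""
    return replace(base, condition="GT", artifacts=[])


def mvmt_profile(base: SynthSpec) -> SynthSpec:
    """Full-body-movement preset: ~10% burst coverage, blinks, one
    uncorrelated channel — the dense contamination the pipeline targets."""
    dur = base.duration_s
    n_bursts = max(1, int(round(dur * 0.10)))  # 1-s bursts covering ~10%
    step = dur / (n_bursts + 1)
    intervals = [(round(step * (i + 1), 3), round(step * (i + 1) + 1.0, 3)) for i in range(n_bursts)]
    artifacts = [
        ArtifactSpec("burst", channels=None, intervals=intervals, amplitude=400.0),
        ArtifactSpec("blink", channels=[0, 1]),
        ArtifactSpec("uncorrelated_channel", channels=[base.n_channels - 1]),
    ]
    return replace(base, condition="MVMT", artifacts=artifacts)


def write_openbci_txt(rec: Recording, path) -> None:
    """Emit a Recording in the OpenBCI GUI text dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("%OpenBCI Raw EXG Data\n")
        fh.write(f"%Number of channels = {rec.n_channels}\n")
        fh.write(f"%Sample Rate = {rec.fs:g} Hz\n")
        fh.write("%Board = OpenBCI_GUI$BoardCytonSerialDaisy\n")
        cols = ["Sample Index"]
        cols += [f"EXG Channel {i}" for i in range(rec.n_channels)]
        cols += ["Accel Channel 0", "Timestamp", "Timestamp (Formatted)"]
        fh.write(",".join(cols) + "\n")
        ts = rec.start_time + np.arange(rec.n_samples) / rec.fs * 1000.0
        for i in range(rec.n_samples):
            row = [str(i % 256)]
            row += [f"{v:.4f}" for v in rec.data[:, i]]
            row += ["0.0", f"{ts[i]:.1f}", "1970-01-01"]
            fh.write(",".join(row) + "\n")
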