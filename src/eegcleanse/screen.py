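"""Bad-channel screening.

Four amplitude-based criteria remove unreliable electrodes before ASR:

1. high impedance — mean absolute amplitude above 48,000 µV (poor contact);
2. flatline — no signal variance over any contiguous stretch of ≥ 5 s;
3. low correlation — Pearson correlation with the leave-one-out cross-channel
   median (the "robust signal mean") below 0.85; the correlation is computed
   per 1-s window and summarized by the median over windows, so a transient
   burst (ASR's job) cannot condemn an otherwise healthy channel;
4. noisy — per-channel amplitude (standard deviation over time) a robust
   z-score outlier, |z| > 4, with z computed from the median and scaled MAD
   of the channel amplitudes.

High-impedance removal runs first; the remaining criteria are evaluated on
the surviving channel set, matching the pipeline's two-step accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import Recording

__all__ = [
    "ScreenConfig",
    "ChannelVerdict",
    "ScreenResult",
    "detect_high_impedance",
    "detect_flatline",
    "detect_low_correlation",
    "detect_noisy",
    "screen_channels",
]

MAD_SCALE = 1.4826  # consistent with the normal distribution


@dataclass
class ScreenConfig:
    impedance_threshold_uv: float = 48_000.0
    impedance_use_abs: bool = True  # mean |x| rather than signed mean
    flatline_min_s: float = 5.0
    flatline_var_tol: float = 1e-10  # µV², float noise on digitally flat runs
    corr_threshold: float = 0.85
    corr_window_s: float = 1.0
    z_threshold: float = 4.0
    min_channels: int = 4

    def __post_init__(self) -> None:
        for name in ("impedance_threshold_uv", "flatline_min_s", "corr_threshold", "z_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.corr_threshold <= 1):
            raise ValueError("corr_threshold must lie in (0, 1]")


@dataclass
class ChannelVerdict:
    label: str
    removed: bool = False
    reasons: list[str] = field(default_factory=list)
    statistics: dict[str, float] = field(default_factory=dict)

    def flag(self, reason: str, value: float) -> None:
        if reason not in self.reasons:
            self.reasons.append(reason)
        self.removed = True
        self.statistics[reason] = float(value)


@dataclass
class ScreenResult:
    recording: Recording
    verdicts: list[ChannelVerdict]
    status: str  # "ok" | "excluded"
    n_after_impedance: int
    n_after_noise: int

    @property
    def removed_labels(self) -> list[str]:
        return [v.label for v in self.verdicts if v.removed]


def detect_high_impedance(rec: Recording, cfg: ScreenConfig) -> list[ChannelVerdict]:
    """Flag channels whose mean (absolute) amplitude strictly exceeds the
    impedance threshold."""
    verdicts = [ChannelVerdict(lbl) for lbl in rec.channel_labels]
    amp = (
        np.mean(np.abs(rec.data), axis=1)
        if cfg.impedance_use_abs
        else np.mean(rec.data, axis=1)
    )
    for v, a in zip(verdicts, amp):
        v.statistics["high_impedance"] = float(a)
        if a > cfg.impedance_threshold_uv:
            v.flag("high_impedance", a)
    return verdicts


def _min_sliding_var(x: np.ndarray, w: int) -> float:
    """Minimum variance over all length-w windows, O(n) via cumulative sums."""
    n = x.size
    if w > n:
        return np.inf
    c1 = np.cumsum(np.insert(x, 0, 0.0))
    c2 = np.cumsum(np.insert(x * x, 0, 0.0))
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    var = s2 / w - (s1 / w) ** 2
    return float(np.maximum(var, 0.0).min())


def detect_flatline(rec: Recording, cfg: ScreenConfig) -> list[ChannelVerdict]:
    """Flag channels containing a flat (zero-variance) run of ≥ flatline_min_s."""
    verdicts = [ChannelVerdict(lbl) for lbl in rec.channel_labels]
    w = int(round(cfg.flatline_min_s * rec.fs))
    if rec.n_samples < w:
        rec.log(
            f"screen: recording shorter than {cfg.flatline_min_s:g} s, "
            "flatline criterion skipped"
        )
        return verdicts
    for v, ch in zip(verdicts, rec.data):
        mv = _min_sliding_var(ch, w)
        v.statistics["flatline"] = mv
        if mv <= cfg.flatline_var_tol:
            v.flag("flatline", mv)
    return verdicts


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


def detect_low_correlation(rec: Recording, cfg: ScreenConfig) -> list[ChannelVerdict]:
    """Flag channels poorly correlated with the cross-channel median.

    The reference for each channel is the per-sample median of all *other*
    channels (leave-one-out), so a single bad channel cannot drag its own
    reference towards itself.  The statistic is the median of per-window
    Pearson correlations (window ``corr_window_s``): persistent decoupling is
    flagged, transient bursts are left for ASR.
    """
    verdicts = [ChannelVerdict(lbl) for lbl in rec.channel_labels]
    if rec.n_channels < 3:
        rec.log("screen: fewer than 3 channels, low-correlation criterion skipped")
        return verdicts
    w = int(round(cfg.corr_window_s * rec.fs))
    n_win = max(1, rec.n_samples // w)
    for i, v in enumerate(verdicts):
        others = np.delete(rec.data, i, axis=0)
        ref = np.median(others, axis=0)
        if n_win == 1:
            r = _pearson(rec.data[i], ref)
        else:
            rs = [
                _pearson(rec.data[i, j * w : (j + 1) * w], ref[j * w : (j + 1) * w])
                for j in range(n_win)
            ]
            r = float(np.median(rs))
        v.statistics["low_correlation"] = r
        if r < cfg.corr_threshold:
            v.flag("low_correlation", r)
    return verdicts


def detect_noisy(rec: Recording, cfg: ScreenConfig) -> list[ChannelVerdict]:
    """Flag amplitude outliers via a robust z-score on per-channel SD."""
    verdicts = [ChannelVerdict(lbl) for lbl in rec.channel_labels]
    if rec.n_channels < 3:
        rec.log("screen: fewer than 3 channels, noisy criterion skipped")
        return verdicts
    amp = np.std(rec.data, axis=1)
    med = np.median(amp)
    mad = np.median(np.abs(amp - med))
    if mad == 0:
        rec.log("screen: zero MAD of channel amplitudes, noisy criterion skipped")
        return verdicts
    z = (amp - med) / (MAD_SCALE * mad)
    for v, zi in zip(verdicts, z):
        v.statistics["noisy"] = float(zi)
        if abs(zi) > cfg.z_threshold:
            v.flag("noisy", zi)
    return verdicts


def _merge(into: dict[str, ChannelVerdict], new: list[ChannelVerdict]) -> None:
    for v in new:
        tgt = into[v.label]
        tgt.statistics.update(v.statistics)
        for reason in v.reasons:
            tgt.flag(reason, v.statistics[reason])


def screen_channels(
    rec: Recording, cfg: ScreenConfig | None = None
) -> ScreenResult:
    """Run the two-step screening and drop all flagged channels.

    High-impedance channels are removed first; flatline, low-correlation and
    noisy statistics are then computed on the survivors only.  If fewer than
    ``min_channels`` survive, the result carries status ``"excluded"`` (an
    explicit status, not an exception) — the session cannot support ICA.
    """
    cfg = cfg or ScreenConfig()
    verdicts = {lbl: ChannelVerdict(lbl) for lbl in rec.channel_labels}

    _merge(verdicts, detect_high_impedance(rec, cfg))
    survivors = [lbl for lbl in rec.channel_labels if not verdicts[lbl].removed]
    n_after_impedance = len(survivors)
    step1 = rec.select_channels(survivors)

    for detector in (detect_flatline, detect_low_correlation, detect_noisy):
        _merge(verdicts, detector(step1, cfg))

    survivors = [lbl for lbl in rec.channel_labels if not verdicts[lbl].removed]
    out = rec.select_channels(survivors)
    ordered = [verdicts[lbl] for lbl in rec.channel_labels]
    removed = [v for v in ordered if v.removed]
    out.log(
        f"screen: removed {len(removed)}/{rec.n_channels} channels "
        f"({', '.join(v.label + ':' + '+'.join(v.reasons) for v in removed) or 'none'})"
    )
    status = "ok" if len(survivors) >= cfg.min_channels else "excluded"
    if status == "excluded":
        out.log(
            f"screen: only {len(survivors)} clean channels "
            f"(< {cfg.min_channels}), session excluded"
        )
    return ScreenResult(
        recording=out,
        verdicts=ordered,
        status=status,
        n_after_impedance=n_after_impedance,
        n_after_noise=len(survivors),
    )
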