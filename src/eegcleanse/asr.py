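"""Artifact Subspace Reconstruction (ASR).

ASR calibrates a statistical model on clean stretches of the recording and
reconstructs transient high-variance subspace components in contaminated
windows.  The variant implemented here is the fixed (non-Riemannian) one:

1. *Clean reference selection* — the recording is cut into calibration
   windows; a window is clean when every channel's windowed RMS has a robust
   z-score within configurable bounds.
2. *Calibration* — principal components V and the mixing estimate
   M = sqrtm(C) are taken from the covariance C of the clean reference;
   each component receives an RMS threshold mean + burst_criterion · sd over
   the calibration windows.
3. *Correction* — in sliding detection windows, components whose RMS exceeds
   their threshold are reconstructed from the retained subspace through
   R = M · pinv(keep ∘ (VᵀM)) · Vᵀ, which is the identity when nothing is
   flagged; overlapping windows are blended with a raised-cosine taper.
4. *Window rejection* — windows where more than ``window_criterion`` of the
   channels still exceed their (gross, ``reject_z``-sigma) calibration
   bounds after correction are removed from the time axis.

ASR runs on channel-screened, *unfiltered* data; high-pass filtering comes
afterwards so that brief high-amplitude artifacts are never smeared across
time by a sharp filter before ASR sees them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import welch

from .recording import Recording, SessionExcluded

__all__ = [
    "AsrConfig",
    "AsrState",
    "CalibrationError",
    "find_clean_reference",
    "calibrate_asr",
    "apply_asr",
    "reject_bad_windows",
    "run_asr",
]


class CalibrationError(ValueError):
    pass


@dataclass
class AsrConfig:
    """ASR parameters; the four named criteria follow the pipeline defaults."""

    channel_criterion: float = 0.85
    line_noise_criterion: float = 4.0
    burst_criterion: float = 3.0
    window_criterion: float = 0.05
    calib_window_s: float = 1.0
    detect_window_s: float = 0.25
    detect_overlap: float = 0.5
    ref_z_bounds: tuple[float, float] = (-3.5, 5.0)
    reject_z: float = 7.0  # channel-RMS bound for window rejection

    def __post_init__(self) -> None:
        if self.burst_criterion <= 0:
            raise ValueError("burst_criterion must be positive")
        if not (0 < self.window_criterion < 1):
            raise ValueError("window_criterion must lie in (0, 1)")
        if not (0 <= self.detect_overlap < 1):
            raise ValueError("detect_overlap must lie in [0, 1)")


@dataclass
class AsrState:
    """Calibrated ASR model for one session."""

    components: np.ndarray  # (k, k) eigenvectors of calibration covariance, columns
    mixing_estimate: np.ndarray  # (k, k) sqrtm of calibration covariance
    component_thresholds: np.ndarray  # (k,) RMS bound per component
    channel_thresholds: np.ndarray  # (k,) RMS bound per channel (window rejection)
    channel_means: np.ndarray  # (k,) mean removed before calibration
    calibration_mask: np.ndarray  # (n_samples,) bool
    channel_labels: list[str] = field(default_factory=list)

    @property
    def clean_fraction(self) -> float:
        return float(np.mean(self.calibration_mask))


def _window_rms(x: np.ndarray, w: int) -> np.ndarray:
    """RMS of consecutive non-overlapping length-w windows, per row."""
    n = x.shape[-1] // w
    if n == 0:
        raise CalibrationError("signal shorter than one calibration window")
    trimmed = x[..., : n * w].reshape(*x.shape[:-1], n, w)
    return np.sqrt(np.mean(trimmed**2, axis=-1))


def _robust_z(values: np.ndarray, axis: int = -1) -> np.ndarray:
    med = np.median(values, axis=axis, keepdims=True)
    mad = np.median(np.abs(values - med), axis=axis, keepdims=True)
    dev = values - med
    with np.errstate(divide="ignore", invalid="ignore"):
        z = dev / (1.4826 * mad)
    # channels whose windowed RMS is perfectly constant: deviation 0 -> z 0
    z = np.where(mad == 0, np.where(dev == 0, 0.0, np.inf * np.sign(dev)), z)
    return z


def _log_precheck_channels(rec: Recording, cfg: AsrConfig) -> None:
    """ChannelCriterion / LineNoiseCriterion checks on the calibration data.

    Channel removal is the screening stage's job; these are logged for
    parameter fidelity only.
    """
    if rec.n_channels < 3:
        return
    for i, lbl in enumerate(rec.channel_labels):
        ref = np.median(np.delete(rec.data, i, axis=0), axis=0)
        a = rec.data[i] - rec.data[i].mean()
        b = ref - ref.mean()
        denom = np.sqrt((a @ a) * (b @ b))
        r = (a @ b) / denom if denom > 0 else 0.0
        if r < cfg.channel_criterion:
            rec.log(
                f"asr: ChannelCriterion fired on {lbl} (r={r:.3f} < "
                f"{cfg.channel_criterion:g}); channel kept (screened earlier)"
            )
    nyq = rec.fs / 2
    if nyq > 45:
        f, p = welch(rec.data, fs=rec.fs, nperseg=min(rec.n_samples, 512))
        band = (f >= 45) & (f <= min(nyq, 65))
        ratio = p[:, band].sum(axis=1) / np.maximum(p.sum(axis=1), 1e-30)
        z = _robust_z(ratio)
        for lbl, zi in zip(rec.channel_labels, np.atleast_1d(z)):
            if zi > cfg.line_noise_criterion:
                rec.log(
                    f"asr: LineNoiseCriterion fired on {lbl} (z={zi:.2f} > "
                    f"{cfg.line_noise_criterion:g}); channel kept (screened earlier)"
                )


def find_clean_reference(rec: Recording, cfg: AsrConfig | None = None) -> np.ndarray:
    """Boolean per-sample mask of the clean calibration reference.

    A calibration window is clean when, on every channel, the robust z-score
    of its RMS lies within ``ref_z_bounds``.  The marked fraction is what the
    pipeline reports as the clean-reference percentage of the session.
    """
    cfg = cfg or AsrConfig()
    w = int(round(cfg.calib_window_s * rec.fs))
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    if np.allclose(data, 0):
        raise CalibrationError("recording has zero variance; cannot calibrate ASR")
    rms = _window_rms(data, w)  # (k, n_windows)
    z = _robust_z(rms, axis=1)
    lo, hi = cfg.ref_z_bounds
    clean_windows = np.all((z >= lo) & (z <= hi), axis=0)
    if not clean_windows.any():
        raise CalibrationError(
            "no calibration window qualified as clean; relax ref_z_bounds or "
            "lower the artifact load before ASR"
        )
    mask = np.zeros(rec.n_samples, dtype=bool)
    for j, ok in enumerate(clean_windows):
        if ok:
            mask[j * w : (j + 1) * w] = True
    # the trailing partial window inherits the verdict of its predecessor
    if rec.n_samples > clean_windows.size * w and clean_windows[-1]:
        mask[clean_windows.size * w :] = True
    rec.log(f"asr: clean reference covers {100 * mask.mean():.2f}% of samples")
    return mask


def calibrate_asr(
    rec: Recording, mask: np.ndarray, cfg: AsrConfig | None = None
) -> AsrState:
    """Calibrate the ASR model on the masked clean reference."""
    cfg = cfg or AsrConfig()
    if mask.sum() < 5 * rec.fs:
        raise CalibrationError(
            f"clean reference covers only {mask.sum() / rec.fs:.1f} s (< 5 s)"
        )
    means = rec.data.mean(axis=1, keepdims=True)
    calib = (rec.data - means)[:, mask]
    cov = np.cov(calib)
    lam, vec = np.linalg.eigh(cov)
    lam = np.maximum(lam, 0.0)
    rank = int(np.sum(lam > lam.max() * 1e-12))
    if rank < rec.n_channels:
        rec.log(
            f"asr: calibration covariance rank {rank} < {rec.n_channels}; "
            "proceeding with pseudo-inverse reconstruction"
        )
    mixing = vec @ np.diag(np.sqrt(lam)) @ vec.T  # sqrtm of the covariance
    # thresholds are consumed by detection windows, so the calibration RMS
    # statistics must be computed at the detection window length
    w = int(round(cfg.detect_window_s * rec.fs))
    comp = vec.T @ calib
    comp_rms = _window_rms(comp, w)
    thresholds = comp_rms.mean(axis=1) + cfg.burst_criterion * comp_rms.std(axis=1)
    # window rejection looks for gross, pervasive contamination that the
    # subspace reconstruction could not fix; its channel-level bound sits far
    # beyond the burst-detection bound so chance fluctuations never trigger it
    chan_rms = _window_rms(calib, w)
    chan_thresholds = chan_rms.mean(axis=1) + cfg.reject_z * chan_rms.std(axis=1)
    _log_precheck_channels(rec, cfg)
    return AsrState(
        components=vec,
        mixing_estimate=mixing,
        component_thresholds=thresholds,
        channel_thresholds=chan_thresholds,
        channel_means=means[:, 0],
        calibration_mask=mask.copy(),
        channel_labels=list(rec.channel_labels),
    )


def _detect_windows(n: int, w: int, hop: int) -> list[int]:
    starts = list(range(0, max(n - w, 0) + 1, hop))
    if not starts:
        return [0]
    if starts[-1] != n - w:
        starts.append(n - w)
    return starts


def apply_asr(
    rec: Recording, state: AsrState, cfg: AsrConfig | None = None
) -> tuple[Recording, np.ndarray]:
    """Reconstruct burst-contaminated subspace components window by window.

    Returns the corrected recording and a per-sample boolean mask of samples
    inside any modified window.  Clean stationary input passes through almost
    untouched; the fraction of the mask is the reported reconstruction rate.
    """
    cfg = cfg or AsrConfig()
    if state.channel_labels != rec.channel_labels:
        raise ValueError(
            "ASR state was calibrated on a different channel set: "
            f"{state.channel_labels} vs {rec.channel_labels}"
        )
    V = state.components
    M = state.mixing_estimate
    thr = state.component_thresholds
    k, n = rec.data.shape
    w = min(int(round(cfg.detect_window_s * rec.fs)), n)
    hop = max(1, int(round(w * (1 - cfg.detect_overlap))))

    x = rec.data - state.channel_means[:, None]
    out = np.zeros_like(x)
    weight = np.zeros(n)
    taper = np.hanning(w) + 1e-3
    reconstructed = np.zeros(n, dtype=bool)

    for start in _detect_windows(n, w, hop):
        seg = x[:, start : start + w]
        comp = V.T @ seg
        rms = np.sqrt(np.mean(comp**2, axis=1))
        bad = rms > thr
        if bad.any():
            U = V.T @ M
            U[bad, :] = 0.0
            R = M @ np.linalg.pinv(U) @ V.T
            seg = R @ seg
            reconstructed[start : start + w] = True
        out[:, start : start + w] += seg * taper
        weight[start : start + w] += taper

    out /= weight
    out += state.channel_means[:, None]
    frac = float(reconstructed.mean())
    result = rec.with_data(
        out, note=f"asr: reconstructed {100 * frac:.2f}% of samples"
    )
    return result, reconstructed


def reject_bad_windows(
    rec: Recording, state: AsrState, cfg: AsrConfig | None = None
) -> tuple[Recording, list[tuple[float, float]]]:
    """Drop windows still pervasively noisy after reconstruction.

    A (non-overlapping) detection window is dropped when the fraction of
    *channels* whose windowed RMS still exceeds their calibration threshold
    is greater than ``window_criterion`` — pervasive contamination that the
    subspace reconstruction could not fix.  Dropped intervals are returned in
    seconds relative to the recording start.  If every window is dropped the
    session is excluded.
    """
    cfg = cfg or AsrConfig()
    thr = state.channel_thresholds
    k, n = rec.data.shape
    w = min(int(round(cfg.detect_window_s * rec.fs)), n)
    x = rec.data - state.channel_means[:, None]

    keep = np.ones(n, dtype=bool)
    dropped: list[tuple[float, float]] = []
    for start in range(0, n, w):
        seg = x[:, start : start + w]
        rms = np.sqrt(np.mean(seg**2, axis=1))
        frac_exceed = float(np.mean(rms > thr))
        if frac_exceed > cfg.window_criterion:
            stop = min(start + w, n)
            keep[start:stop] = False
            dropped.append((start / rec.fs, stop / rec.fs))
    if not keep.any():
        raise SessionExcluded("asr", "every window flagged as pervasively noisy")
    out = rec.with_data(
        rec.data[:, keep],
        note=(
            f"asr: rejected {len(dropped)} windows "
            f"({(n - keep.sum()) / rec.fs:.2f} s) with pervasive noise"
        ),
    )
    return out, dropped


def run_asr(
    rec: Recording, cfg: AsrConfig | None = None
) -> tuple[Recording, AsrState, np.ndarray, list[tuple[float, float]]]:
    """Full ASR stage: reference, calibration, correction, window rejection."""
    cfg = cfg or AsrConfig()
    mask = find_clean_reference(rec, cfg)
    state = calibrate_asr(rec, mask, cfg)
    corrected, reconstructed = apply_asr(rec, state, cfg)
    final, dropped = reject_bad_windows(corrected, state, cfg)
    return final, state, reconstructed, dropped
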