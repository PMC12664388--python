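"""Validation metrics for cleaned EEG.

Unit-invariant signal metrics (spectral entropy, relative band power, an
alpha-based SNR proxy, correlation to the raw signal, effective matrix
rank), the two normalizations used before computing them (z-score and
channel-wise L2), IC-based summaries, and the paired comparison statistics
(paired t, two-sided p, Cohen's d on differences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import welch
from scipy.stats import ttest_rel

from .recording import Recording
from .vote import BRAIN, IcProbabilityTable, VoteDecision

__all__ = [
    "zscore_normalize",
    "l2_normalize",
    "spectral_entropy",
    "band_power",
    "snr_proxy",
    "correlation_to_raw",
    "effective_rank",
    "ic_summary",
    "PairedComparison",
    "paired_compare",
    "ALPHA_BAND",
    "BETA_BAND",
]

ALPHA_BAND = (8.0, 13.0)
BETA_BAND = (13.0, 30.0)

# Welch defaults: 2-s Hamming windows, 50% overlap
_WELCH_WINDOW_S = 2.0


def _welch(data: np.ndarray, fs: float):
    nperseg = min(int(round(_WELCH_WINDOW_S * fs)), data.shape[-1])
    return welch(data, fs=fs, window="hamming", nperseg=nperseg)


def zscore_normalize(rec: Recording) -> Recording:
    """Per-channel mean 0, SD 1 (population SD)."""
    sd = rec.data.std(axis=1)
    flat = np.where(sd == 0)[0]
    if flat.size:
        raise ValueError(
            f"constant channel(s) cannot be z-scored: "
            f"{[rec.channel_labels[i] for i in flat]}"
        )
    out = (rec.data - rec.data.mean(axis=1, keepdims=True)) / sd[:, None]
    return rec.with_data(out, note="metrics: z-score normalized")


def l2_normalize(rec: Recording) -> Recording:
    """Per-channel unit Euclidean norm across time."""
    norm = np.linalg.norm(rec.data, axis=1)
    norm = np.where(norm == 0, 1.0, norm)
    return rec.with_data(rec.data / norm[:, None], note="metrics: L2 normalized")


def spectral_entropy(rec: Recording | np.ndarray, fs: float | None = None) -> float:
    """Shannon entropy (bits) of the Welch PSD as a probability mass.

    Maximal (log2 of the bin count) for a flat white spectrum, small for a
    spectrum concentrated on few bins; averaged over channels.  Rectangular
    segments are used here (unlike the tapered ones for band power): a taper
    smears even a pure oscillation over its mainlobe bins and would floor the
    entropy near one bit, whereas rectangular segments let a sustained
    oscillation collapse onto essentially a single bin.
    """
    data, fs = _as_array(rec, fs)
    nperseg = min(int(round(_WELCH_WINDOW_S * fs)), data.shape[-1])
    f, p = welch(data, fs=fs, window="boxcar", nperseg=nperseg)
    total = p.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("zero total power; spectral entropy undefined")
    pm = p / total
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(pm > 0, pm * np.log2(pm), 0.0).sum(axis=-1)
    return float(np.mean(h))


def _as_array(rec, fs):
    if isinstance(rec, Recording):
        return np.atleast_2d(rec.data), rec.fs
    if fs is None:
        raise ValueError("fs is required for array input")
    return np.atleast_2d(np.asarray(rec, dtype=float)), fs


def band_power(
    rec: Recording | np.ndarray, band: tuple[float, float], fs: float | None = None
) -> float:
    """Welch-integrated power in ``band`` relative to total power."""
    data, fs = _as_array(rec, fs)
    lo, hi = band
    if not (0 <= lo < hi <= fs / 2):
        raise ValueError(f"band {band} must be within (0, {fs / 2}) Hz")
    f, p = _welch(data, fs)
    sel = (f >= lo) & (f < hi)
    if not sel.any():
        raise ValueError(f"band {band} contains no PSD bins")
    total = p.sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError("zero total power")
    return float(np.mean(p[..., sel].sum(axis=-1) / total))


def snr_proxy(rec: Recording | np.ndarray, fs: float | None = None) -> float:
    """Relative alpha-band power, a bounded [0, 1] signal-quality surrogate."""
    return band_power(rec, ALPHA_BAND, fs)


def correlation_to_raw(clean: Recording, raw: Recording) -> float:
    """Mean per-channel Pearson correlation between cleaned and raw data."""
    if clean.channel_labels != raw.channel_labels:
        raise ValueError("channel sets differ between cleaned and raw recordings")
    if clean.n_samples != raw.n_samples:
        raise ValueError(
            f"length mismatch: cleaned {clean.n_samples} vs raw {raw.n_samples} "
            "samples (align/trim the raw recording first)"
        )
    a = clean.data - clean.data.mean(axis=1, keepdims=True)
    b = raw.data - raw.data.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    denom = np.where(denom == 0, 1.0, denom)
    r = (a * b).sum(axis=1) / denom
    return float(np.mean(r))


def effective_rank(rec: Recording | np.ndarray, tol: float = 1e-7) -> int:
    """Number of singular values above ``tol`` times the largest."""
    data = rec.data if isinstance(rec, Recording) else np.atleast_2d(rec)
    s = np.linalg.svd(data - data.mean(axis=1, keepdims=True), compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s > tol * s[0]))


def ic_summary(
    tables: list[IcProbabilityTable],
    decisions: list[VoteDecision],
    p_brain: float = 0.7,
) -> dict:
    """Summaries over retained ICs.

    brain_fraction is the mean Brain probability across retained ICs (mean
    over versions per IC); n_brain_ics counts retained ICs with Brain
    probability ≥ ``p_brain`` in any version; n_artifact_ics counts retained
    ICs whose (version-mean) argmax is non-Brain.
    """
    retained = [d for d in decisions if d.retained]
    if not retained:
        return {
            "brain_fraction": None,
            "artifact_fraction": None,
            "n_brain_ics": 0,
            "n_artifact_ics": 0,
        }
    mean_rows = np.mean([t.probs for t in tables], axis=0)  # (n_ics, 7)
    idx = [d.ic_index for d in retained]
    brain_fraction = float(np.mean(mean_rows[idx, BRAIN]))
    n_brain = sum(max(d.per_version_brain_p) >= p_brain for d in retained)
    n_artifact = sum(int(np.argmax(mean_rows[i])) != BRAIN for i in idx)
    return {
        "brain_fraction": brain_fraction,
        "artifact_fraction": 1.0 - brain_fraction,
        "n_brain_ics": int(n_brain),
        "n_artifact_ics": int(n_artifact),
    }


@dataclass
class PairedComparison:
    t: float
    p: float
    d: float
    n: int
    degenerate: bool = False


def paired_compare(a, b) -> PairedComparison:
    """Paired t-test and Cohen's d on the differences a - b.

    Zero-variance differences are a degenerate case (no spread to test
    against): identical samples report t = 0, d = 0 with the degenerate flag
    set and an undefined (NaN) p-value; a constant non-zero shift reports
    signed infinities.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        m = diff.mean()
        val = 0.0 if m == 0 else math.copysign(math.inf, m)
        return PairedComparison(t=val, p=float("nan"), d=val, n=n, degenerate=True)
    res = ttest_rel(a, b)
    d = float(diff.mean() / sd)
    return PairedComparison(
        t=float(res.statistic), p=float(res.pvalue), d=d, n=n, degenerate=False
    )
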