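# Methods

This note documents the models and procedures implemented in `eegcleanse`,
the parameters that matter, the numerical choices made where the design was
open, and what the synthetic-data tests do and do not demonstrate.

## Signal model and timeline conventions

A recording is a channels × samples matrix in µV at a nominal sampling rate
(125 Hz for the 16-channel Cyton+Daisy configuration). Logger timestamps
jitter row to row, so sample time is defined as the first parsed timestamp
plus index/fs; all intervals are half-open `[start, end)` in seconds
relative to the recording start, with 0-based sample indices. Timestamps in
metadata are integer milliseconds since epoch. Malformed rows in raw text
are dropped and counted, never interpolated — a conservative choice that
keeps the sample→time mapping exact and auditable.

The gameplay buffer (`buffer_s`, default 2 s) pads the trimmed interval on
both sides to cover preparatory and post-task activity; per-mini-game time
adjustments default to 0 s and come from the session metadata. Both are
configuration, not constants, and are written to the provenance log.

## Channel screening

Four criteria, two steps. High-impedance screening runs first: a channel is
removed when its mean **absolute** amplitude strictly exceeds 48,000 µV. The
absolute value matters — a signed mean would let a large symmetric artifact
average to zero. The remaining criteria are then evaluated only on the
survivors, so their cross-channel statistics are not polluted by saturated
electrodes:

- **Flatline** — any contiguous run with variance ≤ 1e-10 µV² lasting
  ≥ 5 s (computed as a minimum over sliding 5-s windows in O(n); the
  tolerance absorbs float noise on digitally constant segments).
- **Low correlation** — the reference for channel i is the per-sample
  median of all *other* channels (leave-one-out, so a bad channel cannot
  drag its own reference). The statistic is the **median of per-1-s-window
  Pearson correlations** with that reference, flagged below 0.85. The
  windowed median is deliberate: a global correlation collapses for every
  channel during dense motion bursts, which are transient events that the
  ASR stage — not channel removal — must handle; the median over windows
  measures the channel's persistent behaviour.
- **Noisy** — per-channel amplitude is the SD over time; the robust z-score
  uses the median and 1.4826·MAD across channels, flagged at |z| > 4. A
  silent channel is just as much an amplitude outlier as a screaming one,
  and is flagged by the same rule.

A session with fewer than `min_channels` (default 4 — below that an ICA
decomposition is meaningless) survivors is marked *excluded* as an explicit
status, not an exception, because batch processing must continue past it.

## Artifact Subspace Reconstruction

The variant is the fixed (non-Riemannian) subspace one.

**Clean reference.** The session is cut into 1-s calibration windows; per
channel, windowed RMS values are converted to robust z-scores, and a window
is clean iff every channel lies within `ref_z_bounds` (default −3.5 … +5,
asymmetric because artifacts inflate amplitude far more often than they
suppress it). The clean fraction is a reported quantity of interest.

**Calibration.** With C the covariance of the clean reference (channel
means removed; means are restored on output), the model keeps the
eigenvectors V of C and the mixing estimate M = C^(1/2). Every principal
component receives the RMS threshold mean + `burst_criterion`·sd over
calibration windows, where the RMS statistics are computed **at the
detection-window length** — thresholds estimated on longer windows would be
systematically tight for shorter detection windows, because RMS variance
grows as windows shrink.

**Correction.** Detection windows are 0.25 s with 50 % overlap. In each
window the component RMS vector is compared to the thresholds; if any
component exceeds, the window is reconstructed with
R = M · pinv(keep ∘ (VᵀM)) · Vᵀ, where `keep` zeroes the rows of flagged
components — the flagged directions are re-estimated from the retained
subspace through the calibration correlation structure. R is exactly the
identity when nothing is flagged, so as `burst_criterion → ∞` the stage
converges to a no-op. Overlapping windows are blended with a raised-cosine
taper. The 0.25-s window is a selectivity choice: any window touching a
burst is reconstructed whole, so the modified region exceeds the true burst
by one window length per side; 0.25 s keeps that halo below half the burst
duration for second-scale bursts.

Under a mean + 3σ rule, a few per-mille of component-windows exceed their
thresholds by chance even on perfectly clean data; reconstruction fractions
of a few percent are therefore the no-artifact baseline, and reported
fractions should be read against it.

**Window rejection.** After correction, non-overlapping windows are dropped
when more than `window_criterion` (0.05) of the **channels** still exceed
their per-channel calibration bound. That bound uses a much larger
multiplier (`reject_z` = 7): with 16 channels and a 5 % criterion, a single
exceeding channel condemns a window, so the bound must be far enough out
that chance fluctuations never reach it — rejection is for gross, pervasive
contamination the subspace reconstruction could not fix.

ASR runs on channel-screened, *unfiltered* data, and high-pass filtering
runs afterwards; filtering first would smear brief high-amplitude
transients across time through the sharp filter kernel.

## High-pass filtering

Linear-phase FIR, order 208, Hamming window; cutoff 0.5 Hz for sessions
shorter than `duration_threshold_s` (default 120 s, configurable — short
segments have too few slow cycles to sacrifice) and 1.0 Hz otherwise, with
the boundary itself mapping to 1.0 Hz. The kernel is designed by spectral
inversion — a unit-DC-gain windowed-sinc low-pass subtracted from a
centered impulse — which pins H(0) to exactly zero even though the 0.5 Hz
cutoff is far narrower than the transition band a 208-tap window can
realize. Zero phase is obtained by single-pass centered convolution with
the symmetric kernel (group delay compensated exactly), reflection padding
at the edges, output length equal to input length.

## Dual ICA and cross-application

Extended infomax (sub/super-Gaussian switching, learning-rate annealing,
at most 512 iterations) is fit independently on the ASR-cleaned and the
filtered data. Before fitting, data are centered per channel and sphered by
the inverse symmetric square root of the covariance restricted to its
numerical rank; rank deficiency (e.g. after subspace reconstruction)
reduces the decomposition to the signal subspace with a warning rather than
failing. `unmixing = weights · sphere`; the mixing matrix is always
recomputed as the pseudo-inverse of the unmixing when a model is embedded
into a target recording. Components are ordered by descending explained
channel-space variance so indices are stable across reruns, and the seed
(default 97) is recorded in the model; identical input and seed reproduce
the weights bit for bit.

A fit is refused (session excluded) below 20·k² samples for k channels —
below that the decomposition is statistically under-determined.

Three mappings feed the voting stage: clean→clean, filtered→filtered,
filtered→clean. The two filtered-model mappings share component indices by
construction; the clean-model table is aligned onto the filtered basis by
Hungarian assignment on absolute activation correlations (computed on the
shared clean recording). If the two models have different ranks no
one-to-one alignment exists and the clean table is omitted from the vote,
logged.

## Component classification and voting

Classification is pluggable: externally computed probability tables (seven
categories: Brain, Muscle, Eye, Heart, Line Noise, Channel Noise, Other)
load from CSV, or the built-in heuristic classifier runs end to end with no
external dependency. The heuristic scores each component from its Welch
spectrum and topography — alpha-band fraction → Brain, 20–45 Hz dominance →
Muscle, low-frequency high-kurtosis transients → Eye, mains-band
concentration → Line Noise, single-channel loading → Channel Noise — and
maps scores to probabilities by softmax, with small constant baselines for
Heart and Other so ambiguous components come out diffuse. It is a
transparent, synthetic stand-in: it makes the pipeline testable and its
behaviour interpretable, and it does not claim agreement with a trained
classifier on real EEG.

Voting thresholds: `p_two` = 0.6 (criterion C1), `p_high` = 0.7 (C2),
`conservative_avg` = 0.5 with equal weights (C3), `p_moderate` = 0.5 (C4),
and a contradiction in C2 means a non-Brain argmax with probability ≥ 0.6
in some version — symmetric with C1's confidence level. The four criteria
are evaluated independently and OR-combined; all criteria that fire are
recorded. Numerical conventions: argmax ties resolve to the earlier
category (Brain first), and the C3 weighted mean is rounded to 12 decimals
before its strict comparison so boundary cases decide identically
regardless of summation order. Retention is monotone in Brain probability
by construction.

The final brain-only signal back-projects the retained components of the
filtered-data model onto the filtered recording (the version downstream
analyses consume); the target is switchable to the ASR-cleaned version.
Zero retained components excludes the session.

## Validation metrics

Z-score (population SD) and channel-wise L2 normalizations precede the
unit-sensitive metrics. Band powers integrate Welch spectra (2-s Hamming
segments, 50 % overlap) over alpha [8, 13) Hz and beta [13, 30) Hz relative
to total power; the SNR proxy is exactly the relative alpha power. Spectral
entropy is the Shannon entropy (bits) of the normalized PSD, computed from
**rectangular** 2-s Welch segments: a taper spreads even a pure oscillation
over its mainlobe bins and floors the entropy near one bit, while
rectangular segments let a sustained oscillation collapse to essentially a
single bin; broadband signals are unaffected. Absolute entropy values
depend on these PSD settings and are comparable only within them.
Effective rank counts singular values above 1e-7 of the largest, on
mean-removed data. The paired comparison reports the paired t statistic,
two-sided p, and Cohen's d as mean(diff)/sd(diff); zero-variance
differences are flagged as degenerate (t = d = 0 with undefined p when the
samples are identical) rather than propagating NaNs silently.

## Synthetic sessions: what they emulate and what they do not

The generator mixes amplitude-modulated alpha (≈10 Hz) and beta (≈20 Hz)
oscillations and 1/f pink noise through a spatially smeared mixing matrix —
rows share a common loading pattern with ±0.1 perturbations, emulating the
high inter-channel correlation volume conduction produces, with evenly
spaced per-channel gains (0.7–1.4, shuffled) for electrode-distance
amplitude spread and the condition number clipped to ≤ 10 so source
recovery is well-posed — plus 2 µV white sensor noise for full rank.
Background amplitudes sit in the physiological ~10–30 µV RMS range.
Artifacts are planted on top with exact masks: constant 96,000 µV offsets
(2× the impedance threshold, unambiguous), whole-channel flatlines,
replaced uncorrelated channels, 100× amplitude outliers, 20× motion-noise
bursts, low-passed positive blink pulses on the frontal channels, and
optional 50 Hz mains. The GT (still) and MVMT (movement) presets share
identical clean sources for a given seed, so the two conditions can be
compared pairwise; MVMT plants ~10 % burst coverage, blinks and one
uncorrelated channel.

Default problem sizes are 16 channels × 60 s at 125 Hz — large enough for
stable ICA (7500 samples ≫ 20·k² for the surviving channel counts) and for
every stage to show its behaviour, small enough that the whole pipeline
runs in seconds.

What passing tests show: each detector recovers its planted artifact
exactly at default thresholds on unambiguous fixtures; ASR suppresses
planted bursts selectively without gross overcorrection; ICA recovers known
mixtures; the voting rule equals its brute-force definition. What they do
not show: performance on real scalp EEG, where artifacts are not additive
Gaussians, sources are not stationary narrowband oscillators, and a trained
component classifier replaces the heuristic. The synthetic results bound
correctness of the machinery, not clinical-grade effectiveness.

## Known limitations

- The heuristic classifier is a test instrument; real deployments should
  load probability tables from a trained classifier.
- Streaming/online operation is out of scope; the pipeline is batch-only.
- Line noise is left to ASR and the classifier's Line Noise category; no
  notch filter is applied.
- Window rejection cuts the time axis; event-locked analyses must use the
  logged dropped intervals to remap event latencies.
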