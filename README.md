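# eegcleanse

Automated, hardware-independent cleaning of EEG recorded during full-body
movement.

EEG captured while participants move freely — exergaming, ambulatory
monitoring, neuroergonomics — is saturated with non-neural artifacts: motion
bursts, muscle activity, eye blinks, failing electrodes, mains interference.
`eegcleanse` turns a raw 16-channel OpenBCI text recording into a
brain-source-only signal through a fixed sequence of stages, each logged so
the provenance of every cleaned sample is auditable:

1. **Ingestion & segmentation** — parse the OpenBCI GUI text dialect,
   synchronize with gameplay timestamps (fixed buffer), cut per-mini-game
   segments labelled by cognitive domain.
2. **Channel screening** — remove channels that are unusable as a whole:
   mean |amplitude| > 48,000 µV (poor contact), zero variance for ≥ 5 s
   (flatline), median windowed correlation with the leave-one-out
   cross-channel median < 0.85, or a per-channel amplitude (SD over time)
   with robust z-score |z| > 4.
3. **Artifact Subspace Reconstruction (ASR)** — calibrate a statistical
   model (principal components V of the clean-reference covariance C, with
   mixing estimate M = C^{1/2}) on the clean fraction of the session, then
   reconstruct, window by window, the components whose RMS exceeds
   mean + 3·sd of the calibration windows; windows still pervasively noisy
   (> 5 % of channels beyond gross bounds) are dropped. Criteria follow the
   EEGLAB naming: ChannelCriterion 0.85, LineNoiseCriterion 4,
   BurstCriterion 3, WindowCriterion 0.05.
4. **Zero-phase high-pass FIR** — order 208, Hamming window, cutoff 0.5 Hz
   for short sessions and 1.0 Hz for long ones, applied *after* ASR so the
   filter never smears transients before ASR sees them.
5. **Dual ICA with cross-application** — extended infomax on both the
   ASR-cleaned and the filtered data; the decompositions are applied across
   versions, yielding three ICA-to-signal mappings (clean→clean,
   filtered→filtered, filtered→clean).
6. **Hybrid brain-IC voting** — each component is classified over the seven
   standard categories (Brain, Muscle, Eye, Heart, Line Noise, Channel
   Noise, Other) per mapping, and retained if **any** of four criteria
   holds: (C1) Brain p ≥ 0.6 in ≥ 2 versions; (C2) Brain p ≥ 0.7 in one
   version and no version contradicts; (C3) weighted mean Brain p above a
   conservative threshold; (C4) a strict majority of versions agree on
   Brain with moderate confidence. Retained components are back-projected
   into channel space.

Because real movement-EEG corpora are rarely shareable, the package ships a
first-class synthetic-session generator (`eegcleanse.synth`): brain-like
sources (amplitude-modulated alpha/beta, pink noise) mixed through a
spatially smeared forward matrix, plus planted artifacts with exact
ground-truth masks — the basis of the entire test suite.

## Worked example

```bash
eegcleanse run-all --synth-seed 7 --out out/
```

```
retained 1/14 ICs; wrote out/brain_only.csv and report.json
```

`report.json` then tells the whole story of the session — which channels
died and why, how much of the recording calibrated ASR, how much was
reconstructed, and the per-component vote trace:

```json
{
  "status": "ok",
  "channels_removed": [
    {"label": "EXG0",  "reasons": ["noisy"]},
    {"label": "EXG15", "reasons": ["low_correlation", "noisy"]}
  ],
  "channel_retention": 0.875,
  "clean_reference_fraction": 0.80,
  "reconstructed_fraction": 0.227,
  "filter_cutoff_hz": 0.5,
  "n_ics": 14,
  "n_retained_ics": 1,
  "ic_decisions": [
    {"ic_index": 0, "retained": true, "fired_criteria": ["C1", "C2", "C3", "C4"],
     "per_version_brain_p": [0.640521, 0.627754, 0.766659]}
  ]
}
```

Reading: of 16 electrodes, the uncorrelated channel EXG15 and the
blink-loaded EXG0 were removed (87.5 % retention); 80 % of the session was
clean enough to calibrate ASR, which reconstructed 22.7 % of the samples
(the planted movement bursts plus their window halos); component 0 — the
dominant alpha source — was retained unanimously by all four voting
criteria, and `brain_only.csv` contains its back-projection.

The same stages are available individually (`eegcleanse ingest / screen /
asr / filter / ica / metrics / synth`) and as library calls
(`eegcleanse.pipeline.run_session`).

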