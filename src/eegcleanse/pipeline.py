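"""End-to-end orchestration of the cleaning pipeline.

Order of operations (deliberate and enforced):

1. channel screening (on raw, unfiltered data);
2. ASR — calibrated and applied on channel-cleaned, *unfiltered* data;
3. zero-phase high-pass filtering (after ASR, never before);
4. dual extended-infomax ICA on the ASR-cleaned and filtered versions, with
   cross-application;
5. IC classification and four-criterion voting;
6. back-projection of the retained brain ICs (onto the filtered version,
   which feeds downstream analysis).

Every stage feeds the :class:`~eegcleanse.recording.CleaningReport`; a
session that cannot continue (too few channels, no clean calibration data,
no decomposition, no brain IC) is returned with status ``"excluded"`` rather
than raising, matching how a batch over many sessions must behave.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import asr as asr_mod
from .asr import AsrConfig, AsrState
from .filters import FilterSpec, choose_cutoff, highpass
from .ica import MappedDecomposition, build_versions
from .recording import CleaningReport, Recording, SessionExcluded
from .screen import ScreenConfig, screen_channels
from .vote import (
    HeuristicClassifier,
    IcProbabilityTable,
    VoteConfig,
    VoteDecision,
    classify_components,
    reconstruct_brain_signal,
    vote_retain,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_session", "align_to_reference"]


@dataclass
class PipelineConfig:
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    asr: AsrConfig = field(default_factory=AsrConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    vote: VoteConfig = field(default_factory=VoteConfig)
    seed: int = 97
    reconstruction_target: str = "filtered"  # "filtered" | "clean"


@dataclass
class PipelineResult:
    status: str  # "ok" | "excluded"
    report: CleaningReport
    final: Recording | None = None
    screened: Recording | None = None
    asr_clean: Recording | None = None
    filtered: Recording | None = None
    asr_state: AsrState | None = None
    decomps: list[MappedDecomposition] = field(default_factory=list)
    tables: list[IcProbabilityTable] = field(default_factory=list)
    decisions: list[VoteDecision] = field(default_factory=list)
    dropped_windows: list[tuple[float, float]] = field(default_factory=list)


def align_to_reference(
    ref: MappedDecomposition, other: MappedDecomposition
) -> np.ndarray | None:
    """Permutation aligning ``other``'s components to ``ref``'s.

    Components of two decompositions are matched greedily-optimally
    (Hungarian assignment) on the absolute correlation of their activation
    time courses; returns the index array ``perm`` such that
    ``other component perm[j]`` corresponds to ``ref component j``, or None
    when the component counts differ (no one-to-one alignment exists).
    """
    if ref.model.n_components != other.model.n_components:
        return None
    a = ref.activations - ref.activations.mean(axis=1, keepdims=True)
    b = other.activations - other.activations.mean(axis=1, keepdims=True)
    a = a / np.maximum(np.linalg.norm(a, axis=1, keepdims=True), 1e-30)
    b = b / np.maximum(np.linalg.norm(b, axis=1, keepdims=True), 1e-30)
    corr = np.abs(a @ b.T)
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty_like(cols)
    perm[rows] = cols
    return perm


def _excluded(report: CleaningReport, stage: str, reason: str) -> PipelineResult:
    report.status = "excluded"
    report.excluded_reason = f"{stage}: {reason}"
    return PipelineResult(status="excluded", report=report)


def run_session(
    rec: Recording,
    cfg: PipelineConfig | None = None,
    classifier=None,
    session_id: str = "",
    condition: str = "",
) -> PipelineResult:
    """Run the full cleaning pipeline on one (already ingested) recording."""
    cfg = cfg or PipelineConfig()
    classifier = classifier or HeuristicClassifier()
    report = CleaningReport(
        session_id=session_id, condition=condition, channels_total=rec.n_channels
    )

    # 1. channel screening
    screened_res = screen_channels(rec, cfg.screen)
    screened = screened_res.recording
    report.channels_removed = [
        {"label": v.label, "reasons": v.reasons, "statistics": v.statistics}
        for v in screened_res.verdicts
        if v.removed
    ]
    report.channel_retention = screened.n_channels / rec.n_channels
    if screened_res.status == "excluded":
        report.history = screened.history
        return _excluded(report, "screen", "insufficient clean channels")

    # 2. ASR on channel-cleaned, unfiltered data
    try:
        asr_clean, state, reconstructed, dropped = asr_mod.run_asr(screened, cfg.asr)
    except (asr_mod.CalibrationError, SessionExcluded) as exc:
        report.history = screened.history
        return _excluded(report, "asr", str(exc))
    report.clean_reference_fraction = state.clean_fraction
    report.reconstructed_fraction = float(np.mean(reconstructed))
    report.dropped_windows_s = float(sum(hi - lo for lo, hi in dropped))

    # 3. high-pass filtering, cutoff adapted to session duration
    cutoff = choose_cutoff(asr_clean.duration_s, cfg.filter)
    filtered = highpass(asr_clean, cfg.filter, cutoff_hz=cutoff)
    report.filter_cutoff_hz = cutoff

    # 4. dual ICA + cross-application
    try:
        decomps = build_versions(asr_clean, filtered, seed=cfg.seed)
    except SessionExcluded as exc:
        report.history = asr_clean.history
        return _excluded(report, "ica", exc.reason)

    # 5. classification; the clean-model table is aligned onto the filtered
    # basis by activation correlation so all tables index the same ICs
    by_mapping = {d.mapping: d for d in decomps}
    tables: list[IcProbabilityTable] = []
    if "filtered_to_filtered" in by_mapping:
        ref = by_mapping["filtered_to_filtered"]
        tables.append(classify_components(ref, classifier))
        if "filtered_to_clean" in by_mapping:
            tables.append(classify_components(by_mapping["filtered_to_clean"], classifier))
        if "clean_to_clean" in by_mapping:
            cc = by_mapping["clean_to_clean"]
            table_cc = classify_components(cc, classifier)
            perm = align_to_reference(by_mapping.get("filtered_to_clean", ref), cc)
            if perm is not None:
                tables.append(
                    IcProbabilityTable(version="clean_to_clean", probs=table_cc.probs[perm])
                )
            else:
                asr_clean.log(
                    "vote: clean decomposition rank differs from filtered; "
                    "its table is not used for voting"
                )
        target_dec = ref if cfg.reconstruction_target == "filtered" else by_mapping.get(
            "filtered_to_clean", ref
        )
    else:
        cc = by_mapping["clean_to_clean"]
        tables.append(classify_components(cc, classifier))
        target_dec = cc

    decisions = vote_retain(tables, cfg.vote)
    report.n_ics = len(decisions)
    report.n_retained_ics = sum(d.retained for d in decisions)
    report.ic_decisions = [
        {
            "ic_index": d.ic_index,
            "retained": d.retained,
            "fired_criteria": d.fired_criteria,
            "per_version_brain_p": [round(p, 6) for p in d.per_version_brain_p],
        }
        for d in decisions
    ]

    # 6. brain-only reconstruction
    try:
        final = reconstruct_brain_signal(target_dec.recording, target_dec.model, decisions)
    except SessionExcluded as exc:
        report.history = filtered.history
        return _excluded(report, "ic_vote", exc.reason)

    report.history = final.history
    return PipelineResult(
        status="ok",
        report=report,
        final=final,
        screened=screened,
        asr_clean=asr_clean,
        filtered=filtered,
        asr_state=state,
        decomps=decomps,
        tables=tables,
        decisions=decisions,
        dropped_windows=dropped,
    )
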