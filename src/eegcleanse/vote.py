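"""Independent-component classification and hybrid brain-IC voting.

Each IC receives a probability row over the seven standard categories
(Brain, Muscle, Eye, Heart, Line Noise, Channel Noise, Other).  The
classifier is pluggable: probability tables computed externally (e.g. by the
ICLabel network inside EEGLAB) can be loaded from CSV, or the built-in
spectral/topographic heuristic classifier can be used for fully
self-contained runs.

An IC is retained as brain-related when, across the available
ICA-to-signal versions, it meets ANY of four criteria:

- C1: Brain probability ≥ 0.6 in at least two versions;
- C2: Brain probability ≥ 0.7 in at least one version and no version
  contradicts it (a contradiction is a non-Brain argmax with probability
  ≥ 0.6 in that version);
- C3: the weighted average Brain probability exceeds a conservative
  threshold (default 0.5, equal weights);
- C4: a strict majority of versions have Brain as the argmax with at least
  moderate confidence (default 0.5).

Ties in the argmax resolve to the earlier category in the canonical order
(so Brain wins exact ties).  All criteria that fire are recorded, not just
the first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import welch
from scipy.stats import kurtosis

from .ica import IcaModel, MappedDecomposition
from .recording import Recording, SessionExcluded

__all__ = [
    "CATEGORIES",
    "IcProbabilityTable",
    "VoteConfig",
    "VoteDecision",
    "HeuristicClassifier",
    "classify_components",
    "load_probability_table",
    "vote_retain",
    "reconstruct_brain_signal",
]

CATEGORIES = (
    "Brain",
    "Muscle",
    "Eye",
    "Heart",
    "Line Noise",
    "Channel Noise",
    "Other",
)
BRAIN = 0


@dataclass
class IcProbabilityTable:
    version: str
    probs: np.ndarray  # (n_ics, 7), rows sum to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(CATEGORIES):
            raise ValueError(f"probs must be (n_ics, {len(CATEGORIES)})")
        if (self.probs < 0).any() or (self.probs > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.probs.sum(axis=1)
        off = np.abs(sums - 1) > 1e-6
        if off.any():
            warnings.warn(
                f"{int(off.sum())} probability rows did not sum to 1; renormalized",
                RuntimeWarning,
                stacklevel=2,
            )
            self.probs = self.probs / sums[:, None]

    @property
    def n_ics(self) -> int:
        return self.probs.shape[0]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.probs, columns=list(CATEGORIES))
        df.insert(0, "ic_index", np.arange(self.n_ics))
        df.to_csv(path, index=False)


def load_probability_table(path, version: str = "external") -> IcProbabilityTable:
    """Load an externally computed probability table from CSV."""
    df = pd.read_csv(path)
    missing = [c for c in CATEGORIES if c not in df.columns]
    if missing:
        raise ValueError(f"probability CSV is missing columns: {missing}")
    return IcProbabilityTable(version=version, probs=df[list(CATEGORIES)].to_numpy())


@dataclass
class VoteConfig:
    p_two: float = 0.6
    p_high: float = 0.7
    conservative_avg: float = 0.5
    p_moderate: float = 0.5
    contradiction_p: float = 0.6
    weights: list[float] | None = None  # per-version; equal when None

    def __post_init__(self) -> None:
        if not (0 < self.p_moderate <= self.p_two <= self.p_high <= 1):
            raise ValueError("need 0 < p_moderate <= p_two <= p_high <= 1")


@dataclass
class VoteDecision:
    ic_index: int
    retained: bool
    fired_criteria: list[str] = field(default_factory=list)
    per_version_brain_p: list[float] = field(default_factory=list)


class HeuristicClassifier:
    """Spectral/topographic stand-in for a trained IC classifier.

    Scores are hand-crafted from component features and mapped to a
    probability row by a softmax: a clear alpha peak votes Brain, dominance
    above 20 Hz votes Muscle, low-frequency high-kurtosis transients vote
    Eye, a 50/60 Hz concentration votes Line Noise, and a topography loading
    onto a single channel votes Channel Noise; Heart and Other carry small
    constant baselines so ambiguous components come out diffuse.  This is a
    synthetic, interpretable classifier for self-contained testing — it does
    not claim equivalence with the ICLabel network.
    """

    def __init__(self, line_freq: float = 50.0):
        self.line_freq = line_freq

    def score_component(
        self, activation: np.ndarray, topography: np.ndarray, fs: float
    ) -> np.ndarray:
        f, p = welch(activation, fs=fs, nperseg=min(activation.size, 256))
        total = p.sum()
        if total <= 0:
            return np.full(len(CATEGORIES), 1.0 / len(CATEGORIES))
        rel = p / total

        def band(lo, hi):
            return float(rel[(f >= lo) & (f < hi)].sum())

        alpha = band(8, 13)
        high = band(20, 45)
        low = band(0, 5)
        line = band(self.line_freq - 2, self.line_freq + 2) + band(58, 62)
        kurt = float(kurtosis(activation))
        topo2 = topography**2
        load = float(topo2.max() / topo2.sum()) if topo2.sum() > 0 else 0.0
        k = topography.size

        scores = np.array(
            [
                5.0 * alpha,  # Brain
                4.0 * high,  # Muscle
                3.0 * low + 0.8 * min(max(kurt - 1.0, 0.0), 3.0),  # Eye
                0.2,  # Heart
                7.0 * line,  # Line Noise
                6.0 * max(0.0, load - 2.0 / k),  # Channel Noise
                1.2,  # Other
            ]
        )
        e = np.exp(scores - scores.max())
        return e / e.sum()

    def __call__(self, dec: MappedDecomposition) -> IcProbabilityTable:
        rows = [
            self.score_component(
                dec.activations[i], dec.model.mixing[:, i], dec.recording.fs
            )
            for i in range(dec.model.n_components)
        ]
        return IcProbabilityTable(version=dec.mapping, probs=np.vstack(rows))


def classify_components(
    dec: MappedDecomposition, classifier=None
) -> IcProbabilityTable:
    """Produce one probability row per IC for one mapped decomposition.

    ``classifier`` is any callable from MappedDecomposition to
    IcProbabilityTable; the built-in heuristic is used when omitted.
    """
    classifier = classifier or HeuristicClassifier()
    table = classifier(dec)
    if table.n_ics != dec.model.n_components:
        raise ValueError(
            f"classifier returned {table.n_ics} rows for "
            f"{dec.model.n_components} components"
        )
    return table


def _argmax_category(row: np.ndarray) -> int:
    # ties resolve to the earlier category (Brain first)
    return int(np.argmax(row))


def vote_retain(
    tables: list[IcProbabilityTable], cfg: VoteConfig | None = None
) -> list[VoteDecision]:
    """Apply the four-criterion OR-combined voting rule per IC."""
    cfg = cfg or VoteConfig()
    if not tables:
        raise ValueError("at least one probability table is required")
    n_ics = tables[0].n_ics
    if any(t.n_ics != n_ics for t in tables):
        raise ValueError("probability tables are not aligned (different IC counts)")
    n_v = len(tables)
    weights = np.asarray(
        cfg.weights if cfg.weights is not None else [1.0] * n_v, dtype=float
    )
    if weights.size != n_v:
        raise ValueError(f"{weights.size} weights for {n_v} versions")
    weights = weights / weights.sum()

    decisions = []
    for i in range(n_ics):
        rows = [t.probs[i] for t in tables]
        brain_p = [float(r[BRAIN]) for r in rows]
        fired = []
        if sum(p >= cfg.p_two for p in brain_p) >= 2:
            fired.append("C1")
        if any(p >= cfg.p_high for p in brain_p):
            contradicted = any(
                _argmax_category(r) != BRAIN and r.max() >= cfg.contradiction_p
                for r in rows
            )
            if not contradicted:
                fired.append("C2")
        # rounded so a mean landing exactly on the threshold decides the same
        # way regardless of float summation order
        if round(float(weights @ np.asarray(brain_p)), 12) > cfg.conservative_avg:
            fired.append("C3")
        n_agree = sum(
            _argmax_category(r) == BRAIN and r[BRAIN] >= cfg.p_moderate for r in rows
        )
        if n_agree > n_v / 2:
            fired.append("C4")
        decisions.append(
            VoteDecision(
                ic_index=i,
                retained=bool(fired),
                fired_criteria=fired,
                per_version_brain_p=brain_p,
            )
        )
    return decisions


def reconstruct_brain_signal(
    rec: Recording, model: IcaModel, decisions: list[VoteDecision]
) -> Recording:
    """Back-project only the retained (brain) ICs into channel space."""
    retained = [d.ic_index for d in decisions if d.retained]
    if not retained:
        raise SessionExcluded("ic_vote", "no brain-related IC retained")
    activations = model.unmixing @ rec.data
    out = model.mixing[:, retained] @ activations[retained]
    return rec.with_data(
        out,
        note=(
            f"vote: retained {len(retained)}/{len(decisions)} ICs "
            f"({', '.join(str(i) for i in retained)})"
        ),
    )
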