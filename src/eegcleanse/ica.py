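"""Dual extended-infomax ICA and cross-application of decompositions.

Two decompositions are computed per session — one on the ASR-cleaned data,
one on the high-pass-filtered data — and the resulting unmixing matrices are
applied across versions, yielding three ICA-to-signal mappings
(clean-to-clean, filtered-to-filtered, filtered-to-clean).  Having the same
component basis viewed against multiple data representations is what makes
the downstream voting strategy robust.

The fitting core is extended infomax (sub/super-Gaussian switching) with
learning-rate annealing; data are centered and sphered to identity
covariance first, so ``unmixing = weights @ sphere``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from mne.preprocessing import infomax

from .recording import Recording, SessionExcluded

__all__ = [
    "IcaModel",
    "MappedDecomposition",
    "fit_extended_infomax",
    "apply_decomposition",
    "build_versions",
]

MAX_ITER = 512
MIN_SAMPLES_FACTOR = 20  # require >= 20 * k^2 samples for a k-channel fit

MAPPINGS = ("clean_to_clean", "filtered_to_filtered", "filtered_to_clean")


@dataclass
class IcaModel:
    """One converged ICA decomposition.

    ``weights`` acts on sphered data; ``unmixing = weights @ sphere`` maps
    channel space to component space, ``mixing`` is its (pseudo-)inverse.
    ``rank`` < n_channels when the input was rank-deficient, in which case
    the decomposition lives on the rank-reduced subspace.
    """

    weights: np.ndarray  # (r, r)
    sphere: np.ndarray  # (r, k)
    unmixing: np.ndarray  # (r, k)
    mixing: np.ndarray  # (k, r)
    source_version: str  # "clean" | "filtered"
    seed: int
    channel_labels: list[str] = field(default_factory=list)
    n_iter: int = 0

    @property
    def rank(self) -> int:
        return self.weights.shape[0]

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]


@dataclass
class MappedDecomposition:
    """An ICA model embedded into one version of the session's data."""

    mapping: str  # one of MAPPINGS
    model: IcaModel
    activations: np.ndarray  # (r, n_samples)
    recording: Recording

    def __post_init__(self) -> None:
        if self.mapping not in MAPPINGS:
            raise ValueError(f"unknown mapping {self.mapping!r}")


def _sphering(data: np.ndarray) -> tuple[np.ndarray, int]:
    """Whitening matrix (r, k) from the eigendecomposition of the covariance.

    Rank deficiency is detected from the eigenvalue spectrum; the sphere then
    projects onto the r-dimensional signal subspace.
    """
    cov = np.cov(data)
    lam, vec = np.linalg.eigh(cov)
    lam = lam[::-1]
    vec = vec[:, ::-1]
    rank = int(np.sum(lam > lam[0] * 1e-10))
    sphere = (vec[:, :rank] / np.sqrt(lam[:rank])).T
    return sphere, rank


def fit_extended_infomax(rec: Recording, seed: int = 97, source_version: str = "clean") -> IcaModel:
    """Fit extended infomax on a recording.

    Data are centered per channel and kept in channels × time layout.  With
    fewer than ``20·k²`` samples the decomposition is statistically
    under-determined and the session is excluded.  Component order is fixed
    to descending explained variance so indices are stable across reruns;
    a fixed seed makes reruns bit-identical.
    """
    k = rec.n_channels
    if rec.n_samples < MIN_SAMPLES_FACTOR * k * k:
        raise SessionExcluded(
            "ica",
            f"{rec.n_samples} samples < {MIN_SAMPLES_FACTOR}·{k}² required "
            "for a stable decomposition",
        )
    centered = rec.data - rec.data.mean(axis=1, keepdims=True)
    sphere, rank = _sphering(centered)
    if rank < k:
        warnings.warn(
            f"data rank {rank} < {k} channels; decomposing the rank-reduced subspace",
            RuntimeWarning,
            stacklevel=2,
        )
    whitened = sphere @ centered
    weights, n_iter = infomax(
        whitened.T,
        extended=True,
        max_iter=MAX_ITER,
        rng=seed,
        return_n_iter=True,
        verbose="error",
    )
    if not np.all(np.isfinite(weights)):
        raise RuntimeError(
            f"extended infomax diverged after {n_iter} iterations "
            f"(non-finite weights)"
        )
    unmixing = weights @ sphere
    mixing = np.linalg.pinv(unmixing)
    # stable component order: descending variance explained in channel space
    acts = unmixing @ centered
    explained = np.sum(mixing**2, axis=0) * np.var(acts, axis=1)
    order = np.argsort(explained)[::-1]
    return IcaModel(
        weights=weights[order],
        sphere=sphere,
        unmixing=unmixing[order],
        mixing=mixing[:, order],
        source_version=source_version,
        seed=seed,
        channel_labels=list(rec.channel_labels),
        n_iter=n_iter,
    )


def apply_decomposition(model: IcaModel, rec: Recording, mapping: str) -> MappedDecomposition:
    """Embed an ICA model into a (possibly different) version of the data.

    The channel set and ordering must match the fit; the mixing matrix is
    recomputed from scratch as the pseudo-inverse of the unmixing matrix, and
    activations are the unmixing applied to the target data.
    """
    if model.channel_labels != rec.channel_labels:
        differing = sorted(
            set(model.channel_labels).symmetric_difference(rec.channel_labels)
        )
        raise ValueError(
            f"channel mismatch between ICA model and target recording: {differing}"
        )
    model.mixing = np.linalg.pinv(model.unmixing)
    activations = model.unmixing @ rec.data
    return MappedDecomposition(
        mapping=mapping, model=model, activations=activations, recording=rec
    )


def build_versions(
    clean_rec: Recording, filt_rec: Recording, seed: int = 97
) -> list[MappedDecomposition]:
    """Fit both session versions and emit the three voting mappings.

    A failed fit degrades gracefully: the mappings that depend on it are
    dropped and the loss logged; if neither fit converges the session is
    excluded.
    """
    if clean_rec.channel_labels != filt_rec.channel_labels:
        raise ValueError("clean and filtered versions must share the channel set")
    models: dict[str, IcaModel] = {}
    for version, rec in (("clean", clean_rec), ("filtered", filt_rec)):
        try:
            models[version] = fit_extended_infomax(rec, seed=seed, source_version=version)
        except (SessionExcluded, RuntimeError) as exc:
            clean_rec.log(f"ica: {version} decomposition failed ({exc})")
    if not models:
        raise SessionExcluded("ica", "no ICA decomposition converged")
    out: list[MappedDecomposition] = []
    if "clean" in models:
        out.append(apply_decomposition(models["clean"], clean_rec, "clean_to_clean"))
    if "filtered" in models:
        out.append(
            apply_decomposition(models["filtered"], filt_rec, "filtered_to_filtered")
        )
        out.append(
            apply_decomposition(models["filtered"], clean_rec, "filtered_to_clean")
        )
    if len(out) < 3:
        clean_rec.log(f"ica: only {len(out)} of 3 mappings available for voting")
    return out
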