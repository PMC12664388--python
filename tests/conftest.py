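"""Shared fixtures: seeded synthetic sessions and ICA test mixtures."""

import numpy as np
import pytest

from eegcleanse import ArtifactSpec, Recording, SynthSpec, generate_session

FS = 125.0

SCREEN_ARTIFACTS = [
    ArtifactSpec("impedance_channel", channels=[2, 9]),
    ArtifactSpec("flatline_channel", channels=[4]),
    ArtifactSpec("uncorrelated_channel", channels=[12]),
    ArtifactSpec("noisy_channel", channels=[7]),
]
SCREEN_BAD = {
    "EXG2": "high_impedance",
    "EXG9": "high_impedance",
    "EXG4": "flatline",
    "EXG12": "low_correlation",
    "EXG7": "noisy",
}

BURST_CHANNELS = [3, 8, 11]
BURST_INTERVALS = [(5, 6), (15, 16), (25, 26), (35, 36), (45, 46), (55, 56)]


@pytest.fixture(scope="session")
def screen_session():
    """60-s, 16-channel session with 2 impedance + 1 flatline +
    1 uncorrelated + 1 noisy planted channels."""
    spec = SynthSpec(seed=11, artifacts=SCREEN_ARTIFACTS)
    return generate_session(spec)


@pytest.fixture(scope="session")
def clean_session():
    """Artifact-free stationary-ish session (still baseline)."""
    return generate_session(SynthSpec(seed=3))


@pytest.fixture(scope="session")
def burst_session():
    """Session with 20x-amplitude 1-s bursts on 3 channels, 10% coverage."""
    spec = SynthSpec(
        seed=5,
        artifacts=[
            ArtifactSpec(
                "burst",
                channels=BURST_CHANNELS,
                intervals=BURST_INTERVALS,
                amplitude=400.0,
            )
        ],
    )
    return generate_session(spec)


def make_ica_mixture(seed: int, n: int = 7500, fs: float = FS):
    """4 channels mixing 4 independent sources: two super-Gaussian, one
    sub-Gaussian sinusoid, one Gaussian noise; condition number <= 5."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    s_laplace = rng.laplace(size=n)
    s_sparse = np.sign(rng.standard_normal(n)) * rng.exponential(1.0, n)
    s_sine = np.sin(2 * np.pi * 10 * t)
    s_gauss = rng.standard_normal(n)
    sources = np.vstack([s_laplace, s_sparse, s_sine, s_gauss])
    sources /= sources.std(axis=1, keepdims=True)
    a = rng.standard_normal((4, 4))
    u, s, vt = np.linalg.svd(a)
    mixing = u @ np.diag(np.maximum(s, s[0] / 5)) @ vt
    rec = Recording(mixing @ sources, fs, [f"C{i}" for i in range(4)])
    return rec, sources, mixing


@pytest.fixture(scope="session")
def ica_mixture():
    return make_ica_mixture(seed=42)
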