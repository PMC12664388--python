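"""Validation metrics: normalizations, spectra, rank, paired statistics."""

import numpy as np
import pytest
from scipy.stats import ttest_rel

from eegcleanse import (
    Recording,
    band_power,
    correlation_to_raw,
    effective_rank,
    ic_summary,
    l2_normalize,
    paired_compare,
    snr_proxy,
    spectral_entropy,
    zscore_normalize,
)
from eegcleanse.metrics import ALPHA_BAND, BETA_BAND
from eegcleanse.vote import IcProbabilityTable, VoteDecision, CATEGORIES

FS = 125.0
N = 12500


def _tone(freq, n=N):
    return np.sin(2 * np.pi * freq * np.arange(n) / FS)


@pytest.fixture(scope="module")
def noise_rec():
    rng = np.random.default_rng(0)
    return Recording(rng.standard_normal((4, N)) * [[1.0], [2.0], [0.5], [3.0]], FS, list("abcd"))


class TestNormalizations:
    def test_zscore_moments(self, noise_rec):
        out = zscore_normalize(noise_rec)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-10
        np.testing.assert_allclose(out.data.std(axis=1), 1.0, atol=1e-9)

    def test_l2_unit_energy(self, noise_rec):
        out = l2_normalize(noise_rec)
        np.testing.assert_allclose((out.data**2).sum(axis=1), 1.0, atol=1e-9)

    def test_rank_invariant_under_both(self, noise_rec):
        r = effective_rank(noise_rec)
        assert effective_rank(zscore_normalize(noise_rec)) == r
        assert effective_rank(l2_normalize(noise_rec)) == r

    def test_constant_channel_rejected_by_zscore(self):
        rec = Recording(np.vstack([np.ones(100), np.arange(100.0)]), FS, ["flat", "x"])
        with pytest.raises(ValueError, match="flat"):
            zscore_normalize(rec)


class TestSpectralEntropy:
    def test_white_noise_near_flat_limit(self, noise_rec):
        n_bins = int(2 * FS) // 2 + 1
        h = spectral_entropy(noise_rec)
        assert h == pytest.approx(np.log2(n_bins), rel=0.05)

    def test_pure_tone_concentrated(self):
        assert spectral_entropy(_tone(10.0)[None, :], FS) < 1.0

    def test_mix_matches_direct_summation(self):
        from scipy.signal import welch

        x = _tone(10.0) + np.random.default_rng(1).standard_normal(N)
        _, p = welch(x, fs=FS, window="boxcar", nperseg=int(2 * FS))
        pm = p / p.sum()
        expected = -np.sum(pm[pm > 0] * np.log2(pm[pm > 0]))
        assert spectral_entropy(x[None, :], FS) == pytest.approx(expected, rel=1e-9)

    def test_zero_power_errors(self):
        with pytest.raises(ValueError):
            spectral_entropy(np.zeros((1, 1000)), FS)


class TestBandPower:
    @pytest.mark.parametrize(
        "freq,band,expected",
        [
            (10.0, ALPHA_BAND, 0.95),
            (20.0, BETA_BAND, 0.95),
        ],
        ids=["alpha-tone", "beta-tone"],
    )
    def test_in_band_tone(self, freq, band, expected):
        assert band_power(_tone(freq)[None, :], band, FS) >= expected

    def test_out_of_band_tone(self):
        assert band_power(_tone(20.0)[None, :], ALPHA_BAND, FS) < 0.05

    def test_tone_pair_splits_evenly(self):
        x = _tone(10.0) + _tone(20.0)
        assert band_power(x[None, :], ALPHA_BAND, FS) == pytest.approx(0.5, abs=0.025)
        assert band_power(x[None, :], BETA_BAND, FS) == pytest.approx(0.5, abs=0.025)

    def test_partition_sums_to_one(self, noise_rec):
        bands = [(0.0, 10.0), (10.0, 30.0), (30.0, 62.5)]
        total = sum(band_power(noise_rec, b) for b in bands)
        assert total == pytest.approx(1.0, abs=0.01)

    def test_scale_invariance(self, noise_rec):
        scaled = noise_rec.with_data(noise_rec.data * np.array([[3.0], [1.0], [7.0], [2.0]]))
        assert band_power(scaled, ALPHA_BAND) == pytest.approx(
            band_power(noise_rec, ALPHA_BAND), rel=1e-9
        )
        assert spectral_entropy(scaled) == pytest.approx(
            spectral_entropy(noise_rec), rel=1e-9
        )

    def test_empty_band_errors(self, noise_rec):
        with pytest.raises(ValueError):
            band_power(noise_rec, (70.0, 80.0))


class TestSnrProxy:
    def test_equals_alpha_band_power(self, noise_rec):
        assert snr_proxy(noise_rec) == band_power(noise_rec, ALPHA_BAND)

    def test_bounds_on_tones(self):
        assert snr_proxy(_tone(10.0)[None, :], FS) >= 0.95
        assert snr_proxy(_tone(20.0)[None, :], FS) < 0.05


class TestCorrelationToRaw:
    def test_self_correlation_is_one(self, noise_rec):
        assert correlation_to_raw(noise_rec, noise_rec) == pytest.approx(1.0)

    def test_negated_is_minus_one(self, noise_rec):
        neg = noise_rec.with_data(-noise_rec.data)
        assert correlation_to_raw(neg, noise_rec) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        a = Recording(rng.standard_normal((1, 10_000)), FS, ["a"])
        b = Recording(rng.standard_normal((1, 10_000)), FS, ["a"])
        assert abs(correlation_to_raw(a, b)) < 0.1

    def test_length_mismatch_errors(self, noise_rec):
        short = noise_rec.slice_samples(0, 1000)
        with pytest.raises(ValueError, match="mismatch"):
            correlation_to_raw(short, noise_rec)


class TestEffectiveRank:
    def test_independent_channels_full_rank(self):
        rng = np.random.default_rng(3)
        assert effective_rank(rng.standard_normal((16, 5000))) == 16

    def test_duplicated_channel_drops_rank_by_one(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((16, 5000))
        x[7] = x[3]
        assert effective_rank(x) == 15

    def test_bounded_by_retained_components(self):
        rng = np.random.default_rng(5)
        mixing = rng.standard_normal((16, 3))
        acts = rng.standard_normal((3, 5000))
        assert effective_rank(mixing @ acts) <= 3


class TestIcSummary:
    @staticmethod
    def _table(rows):
        return IcProbabilityTable("v", np.asarray(rows))

    @staticmethod
    def _decisions(flags):
        return [VoteDecision(i, f, ["C1"] if f else [], [r]) for i, (f, r) in enumerate(flags)]

    def test_pure_brain_fractions(self):
        rows = [[1.0, 0, 0, 0, 0, 0, 0]] * 2
        s = ic_summary([self._table(rows)], self._decisions([(True, 1.0), (True, 1.0)]))
        assert s["brain_fraction"] == pytest.approx(1.0)
        assert s["artifact_fraction"] == pytest.approx(0.0)
        assert s["n_brain_ics"] == 2
        assert s["n_artifact_ics"] == 0

    def test_mixed_component(self):
        rows = [[0.8, 0.2, 0, 0, 0, 0, 0]]
        s = ic_summary([self._table(rows)], self._decisions([(True, 0.8)]))
        assert s["brain_fraction"] == pytest.approx(0.8)
        assert s["n_brain_ics"] == 1

    def test_hand_computed_mixture(self):
        rows = [
            [0.9, 0.1, 0, 0, 0, 0, 0],   # retained, brain argmax
            [0.3, 0.6, 0, 0, 0, 0, 0.1], # retained, muscle argmax
            [0.1, 0.9, 0, 0, 0, 0, 0],   # removed
        ]
        s = ic_summary(
            [self._table(rows)],
            self._decisions([(True, 0.9), (True, 0.3), (False, 0.1)]),
        )
        assert s["brain_fraction"] == pytest.approx((0.9 + 0.3) / 2)
        assert s["n_brain_ics"] == 1
        assert s["n_artifact_ics"] == 1

    def test_zero_retained_marks_undefined(self):
        rows = [[0.1, 0.9, 0, 0, 0, 0, 0]]
        s = ic_summary([self._table(rows)], self._decisions([(False, 0.1)]))
        assert s["brain_fraction"] is None
        assert s["n_brain_ics"] == 0


class TestPairedCompare:
    def test_identical_samples_degenerate_zero(self):
        res = paired_compare([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.t == 0.0 and res.d == 0.0
        assert res.degenerate
        assert np.isnan(res.p)

    def test_constant_shift_with_noise_matches_closed_form(self):
        rng = np.random.default_rng(6)
        b = rng.standard_normal(50)
        a = b + 0.5 + 0.1 * rng.standard_normal(50)
        res = paired_compare(a, b)
        diff = a - b
        expected_t = diff.mean() * np.sqrt(50) / diff.std(ddof=1)
        assert res.t == pytest.approx(expected_t, rel=1e-10)
        assert res.d == pytest.approx(diff.mean() / diff.std(ddof=1), rel=1e-10)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal(200) + 0.3
        b = rng.standard_normal(200)
        res = paired_compare(a, b)
        ref = ttest_rel(a, b)
        assert res.t == pytest.approx(ref.statistic, abs=1e-8)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_exact_constant_shift_flags_degenerate(self):
        res = paired_compare([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert res.t == np.inf

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_compare([1.0, 2.0], [0.0, 1.0])
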