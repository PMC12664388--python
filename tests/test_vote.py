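"""IC probability tables, the heuristic classifier, and the voting rule.

The voting rule is checked against an independently coded brute-force
evaluator of the four retention criteria over an exhaustive probability
grid.
"""

import itertools

import numpy as np
import pytest

from eegcleanse import (
    CATEGORIES,
    HeuristicClassifier,
    IcProbabilityTable,
    Recording,
    SessionExcluded,
    VoteConfig,
    fit_extended_infomax,
    load_probability_table,
    reconstruct_brain_signal,
    vote_retain,
)

FS = 125.0
N_CAT = len(CATEGORIES)
OTHER = CATEGORIES.index("Other")


def brain_table(version, brain_ps):
    """Rows with the given Brain probabilities, residual mass on Other."""
    probs = np.zeros((len(brain_ps), N_CAT))
    probs[:, 0] = brain_ps
    probs[:, OTHER] = 1.0 - np.asarray(brain_ps)
    return IcProbabilityTable(version=version, probs=probs)


def oracle_retain(rows, cfg):
    """Plain-python re-statement of the four OR-combined criteria.

    rows: per-version probability vectors for one IC.  Ties in the argmax go
    to the earlier category, matching the documented convention.
    """

    def argmax(row):
        best = 0
        for j in range(1, len(row)):
            if row[j] > row[best]:
                best = j
        return best

    brain = [row[0] for row in rows]
    n = len(rows)
    c1 = len([p for p in brain if p >= cfg.p_two]) >= 2
    contradiction = False
    for row in rows:
        j = argmax(row)
        if j != 0 and row[j] >= cfg.contradiction_p:
            contradiction = True
    c2 = any(p >= cfg.p_high for p in brain) and not contradiction
    # same documented rounding convention as the implementation
    c3 = round(sum(brain) / n, 12) > cfg.conservative_avg
    c4 = len([row for row in rows if argmax(row) == 0 and row[0] >= cfg.p_moderate]) > n / 2
    return c1 or c2 or c3 or c4


GRID = [round(0.1 * i, 10) for i in range(11)]


class TestProbabilityTable:
    def test_valid_rows_pass_through(self):
        probs = np.full((2, N_CAT), 1.0 / N_CAT)
        t = IcProbabilityTable("v", probs)
        np.testing.assert_array_equal(t.probs, probs)

    def test_off_sum_rows_renormalized_with_warning(self):
        probs = np.full((1, N_CAT), 0.14)  # sums to 0.98
        with pytest.warns(RuntimeWarning, match="renormalized"):
            t = IcProbabilityTable("v", probs)
        assert t.probs.sum() == pytest.approx(1.0)

    def test_csv_round_trip(self, tmp_path):
        t = brain_table("v", [0.7, 0.2])
        p = tmp_path / "probs.csv"
        t.to_csv(p)
        back = load_probability_table(p, version="v")
        np.testing.assert_allclose(back.probs, t.probs, atol=1e-12)

    def test_missing_category_column_errors(self, tmp_path):
        p = tmp_path / "probs.csv"
        p.write_text("ic_index,Brain\n0,1.0\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_probability_table(p)


@pytest.fixture(scope="module")
def hc():
    return HeuristicClassifier()


class TestHeuristicClassifier:

    def test_alpha_oscillation_is_brain(self, hc):
        t = np.arange(7500) / FS
        row = hc.score_component(np.sin(2 * np.pi * 10 * t), np.ones(16), FS)
        assert CATEGORIES[int(np.argmax(row))] == "Brain"

    def test_mains_tone_is_line_noise(self, hc):
        t = np.arange(7500) / FS
        row = hc.score_component(np.sin(2 * np.pi * 50 * t), np.ones(16), FS)
        assert CATEGORIES[int(np.argmax(row))] == "Line Noise"

    def test_single_channel_spikes_are_channel_noise(self, hc):
        topo = np.zeros(16)
        topo[5] = 1.0
        spikes = np.zeros(7500)
        spikes[::250] = 50.0
        row = hc.score_component(spikes, topo, FS)
        assert CATEGORIES[int(np.argmax(row))] == "Channel Noise"

    def test_white_noise_is_diffuse(self, hc):
        noise = np.random.default_rng(0).standard_normal(7500)
        row = hc.score_component(noise, np.ones(16), FS)
        assert row.max() < 0.6
        assert row.sum() == pytest.approx(1.0)


class TestVoteRetain:
    def test_two_confident_versions_fire_c1(self):
        tables = [brain_table(v, [p]) for v, p in zip("abc", (0.65, 0.62, 0.10))]
        (d,) = vote_retain(tables)
        assert d.retained and "C1" in d.fired_criteria

    def test_single_high_confidence_fires_c2(self):
        # residual mass spread over the six non-Brain categories so that no
        # version has a confident non-Brain argmax (nothing contradicts)
        tables = []
        for v, p in zip("abc", (0.75, 0.40, 0.35)):
            row = np.full(N_CAT, (1.0 - p) / (N_CAT - 1))
            row[0] = p
            tables.append(IcProbabilityTable(v, row[None, :]))
        (d,) = vote_retain(tables)
        assert d.retained and "C2" in d.fired_criteria

    def test_contradiction_blocks_c2(self):
        high = brain_table("a", [0.75])
        contra = np.zeros((1, N_CAT))
        contra[0, 1] = 0.8  # Muscle argmax with high confidence
        contra[0, 0] = 0.2
        tables = [high, IcProbabilityTable("b", contra)]
        (d,) = vote_retain(tables)
        assert "C2" not in d.fired_criteria

    def test_uniformly_low_probabilities_removed(self):
        tables = [brain_table(v, [p]) for v, p in zip("abc", (0.20, 0.15, 0.10))]
        (d,) = vote_retain(tables)
        assert not d.retained and d.fired_criteria == []

    def test_exhaustive_grid_matches_oracle(self):
        cfg = VoteConfig()
        for ps in itertools.product(GRID, repeat=3):
            tables = [brain_table(v, [p]) for v, p in zip("abc", ps)]
            (d,) = vote_retain(tables, cfg)
            rows = [t.probs[0] for t in tables]
            assert d.retained == oracle_retain(rows, cfg), ps

    def test_monotone_in_brain_probability(self):
        cfg = VoteConfig()

        def decide(ps):
            tables = [brain_table(v, [p]) for v, p in zip("abc", ps)]
            return vote_retain(tables, cfg)[0].retained

        for ps in itertools.product(GRID, repeat=3):
            if not decide(ps):
                continue
            for axis in range(3):
                if ps[axis] < 1.0:
                    bumped = list(ps)
                    bumped[axis] = round(bumped[axis] + 0.1, 10)
                    assert decide(bumped), (ps, axis)

    def test_zero_thresholds_retain_everything(self):
        cfg = VoteConfig(
            p_two=1e-9, p_high=1e-9, conservative_avg=0.0,
            p_moderate=1e-9, contradiction_p=2.0,
        )
        tables = [brain_table(v, [0.05, 0.3]) for v in "abc"]
        decisions = vote_retain(tables, cfg)
        # every IC passes C1 (any p >= ~0) once contradiction is impossible
        assert all(d.retained for d in decisions)

    def test_max_thresholds_retain_nothing_below_one(self):
        cfg = VoteConfig(
            p_two=1.0, p_high=1.0, conservative_avg=1.0,
            p_moderate=1.0, contradiction_p=1.0,
        )
        tables = [brain_table(v, [0.99, 0.5]) for v in "abc"]
        decisions = vote_retain(tables, cfg)
        assert not any(d.retained for d in decisions)

    def test_single_table_degrades(self):
        (d,) = vote_retain([brain_table("only", [0.8])])
        assert d.retained
        assert "C1" not in d.fired_criteria  # needs two versions
        assert "C4" in d.fired_criteria  # 1 of 1 is a strict majority

    def test_weights_respected_in_c3(self):
        tables = [brain_table(v, [p]) for v, p in zip("ab", (0.9, 0.1))]
        heavy_first = VoteConfig(conservative_avg=0.6, weights=[10.0, 1.0])
        heavy_last = VoteConfig(conservative_avg=0.6, weights=[1.0, 10.0])
        assert "C3" in vote_retain(tables, heavy_first)[0].fired_criteria
        assert "C3" not in vote_retain(tables, heavy_last)[0].fired_criteria

    def test_no_tables_errors(self):
        with pytest.raises(ValueError):
            vote_retain([])

    def test_config_ordering_validated(self):
        with pytest.raises(ValueError):
            VoteConfig(p_two=0.8, p_high=0.6)


@pytest.fixture(scope="module")
def fitted(ica_mixture):
    rec, sources, mixing = ica_mixture
    model = fit_extended_infomax(rec, seed=97)
    return rec, sources, mixing, model


class TestReconstruct:

    @staticmethod
    def _decisions(n, retained_idx):
        from eegcleanse.vote import VoteDecision

        return [
            VoteDecision(i, i in retained_idx, ["C1"] if i in retained_idx else [])
            for i in range(n)
        ]

    def test_all_retained_is_identity(self, fitted):
        rec, _, _, model = fitted
        out = reconstruct_brain_signal(rec, model, self._decisions(4, {0, 1, 2, 3}))
        np.testing.assert_allclose(out.data, rec.data, atol=1e-6)

    def test_zero_retained_excludes(self, fitted):
        rec, _, _, model = fitted
        with pytest.raises(SessionExcluded):
            reconstruct_brain_signal(rec, model, self._decisions(4, set()))

    def test_single_source_isolated(self, fitted):
        rec, sources, mixing, model = fitted
        acts = model.unmixing @ rec.data
        # locate the IC carrying the 10 Hz sinusoid (true source index 2)
        corr = np.abs(
            [np.corrcoef(acts[i], sources[2])[0, 1] for i in range(4)]
        )
        sine_ic = int(np.argmax(corr))
        out = reconstruct_brain_signal(rec, model, self._decisions(4, {sine_ic}))
        sine_proj = np.outer(mixing[:, 2], sources[2])
        noise_proj = np.outer(mixing[:, 3], sources[3])
        r_sine = np.corrcoef(out.data.ravel(), sine_proj.ravel())[0, 1]
        r_noise = np.corrcoef(out.data.ravel(), noise_proj.ravel())[0, 1]
        assert abs(r_sine) >= 0.9
        assert abs(r_noise) < 0.3
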