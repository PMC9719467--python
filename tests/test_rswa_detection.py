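import numpy as np
import pandas as pd
import pytest

from atonia import (DetectionParams, Role, Stage, compute_rms_track,
                    detect_activity_bouts, merge_into_events,
                    score_recording, score_tonic)
from atonia.rswa_detection import (ActivityEvent, Category, RmsTrack,
                                   classify, rescore_phasic_in_tonic,
                                   score_mini_epochs)
from atonia import synthetic_fixtures as sf

import _oracle
from conftest import band_noise, make_channel

STEP = 0.015


def flags_from_spans(spans, n):
    """Boolean slab flags covering the given [start, end) second spans."""
    f = np.zeros(n, dtype=bool)
    for s, e in spans:
        f[round(s / STEP):round(e / STEP)] = True
    return f


def ev(start, end, category=Category.PHASIC, role=Role.MENTALIS, amp=0.1):
    return ActivityEvent(role, start, end, category, amp)


class TestRmsTrack:
    def test_constant_signal(self, params):
        ch = make_channel(np.full(2560, 0.02))
        track = compute_rms_track(ch, 0.0, 10.0, params)
        assert np.allclose(track.values, 0.02)
        assert track.step == STEP
        assert len(track.values) == 665    # last full 30 ms window kept

    def test_square_wave_rms_is_amplitude(self, params):
        a = 0.05
        x = a * np.tile([1.0, -1.0], 1280)
        track = compute_rms_track(make_channel(x), 0.0, 10.0, params)
        assert np.allclose(track.values, a)

    def test_sine_rms_is_a_over_sqrt2(self, params):
        # 32 Hz at 256 Hz sampling: every 30 ms (8-sample) window covers
        # exactly one discrete period, so the window RMS is A/sqrt(2)
        A = 0.1
        t = np.arange(256 * 10) / 256.0
        ch = make_channel(A * np.sin(2 * np.pi * 32 * t))
        track = compute_rms_track(ch, 0.0, 10.0, params)
        assert np.allclose(track.values, A / np.sqrt(2), rtol=0.02)

    def test_short_run_empty_track(self, params):
        ch = make_channel(np.ones(256))
        track = compute_rms_track(ch, 0.0, 0.02, params)
        assert len(track.values) == 0


class TestBouts:
    def test_strict_threshold(self, params):
        track = RmsTrack(values=np.array([0.015, 0.025, 0.025, 0.019]),
                         t0=0.0, step=STEP)
        assert detect_activity_bouts(track, 0.01, params).tolist() == \
            [False, True, True, False]

    def test_exactly_twice_baseline_not_flagged(self, params):
        track = RmsTrack(values=np.array([0.02, 0.02]), t0=0.0, step=STEP)
        assert not detect_activity_bouts(track, 0.01, params).any()

    def test_nonpositive_baseline_rejected(self, params):
        with pytest.raises(ValueError):
            detect_activity_bouts(RmsTrack(np.ones(3), 0.0, STEP), 0.0,
                                  params)


class TestMerge:
    def test_run_not_longer_than_100ms_is_no_event(self, params):
        flags = flags_from_spans([(0.0, 0.09)], 100)
        assert len(merge_into_events(flags, params)) == 0

    def test_gap_shorter_than_250ms_merges(self, params):
        flags = flags_from_spans([(0.0, 0.195), (0.405, 0.6)], 100)
        out = merge_into_events(flags, params)
        assert np.allclose(out, [[0.0, 0.6]])

    def test_gap_of_300ms_splits(self, params):
        flags = flags_from_spans([(0.0, 0.195), (0.495, 0.69)], 100)
        out = merge_into_events(flags, params)
        assert np.allclose(out, [[0.0, 0.195], [0.495, 0.69]])

    def test_short_run_absorbed_by_neighbouring_seed(self, params):
        # 45 ms run alone is no event, but rides along across a small gap
        flags = flags_from_spans([(0.0, 0.15), (0.24, 0.285)], 100)
        out = merge_into_events(flags, params)
        assert np.allclose(out, [[0.0, 0.285]])

    def test_cluster_of_only_short_runs_is_no_event(self, params):
        flags = flags_from_spans([(0.0, 0.06), (0.12, 0.18), (0.24, 0.3)],
                                 100)
        assert len(merge_into_events(flags, params)) == 0

    def test_matches_bruteforce_on_random_flags(self, params, rng):
        for _ in range(300):
            flags = rng.random(rng.integers(5, 200)) < 0.35
            got = merge_into_events(flags, params)
            want = _oracle.events_from_flags(list(flags))
            assert np.allclose(got, np.array(want).reshape(-1, 2))


class TestClassify:
    @pytest.mark.parametrize("duration,cat", [
        (0.2, Category.PHASIC), (5.0, Category.PHASIC),
        (5.05, Category.INTERMEDIATE), (15.0, Category.INTERMEDIATE),
        (15.1, Category.TONIC)])
    def test_duration_boundaries(self, params, duration, cat):
        assert classify(duration, params) is cat


class TestTonic:
    def test_fifty_percent_rule(self, params, rng):
        ch = make_channel(band_noise(rng, 256 * 30, rms=0.05))
        for dur, want in [(14.0, False), (15.0, True), (16.0, True)]:
            tonic, _ = score_tonic(0.0, [ev(2.0, 2.0 + dur)], ch, params)
            assert tonic is want

    def test_accumulates_over_multiple_events(self, params, rng):
        ch = make_channel(band_noise(rng, 256 * 30, rms=0.05))
        events = [ev(1.0, 6.5), ev(10.0, 15.5), ev(20.0, 25.5)]
        tonic, elevated = score_tonic(0.0, events, ch, params)
        assert tonic            # 16.5 s total, no single event >= 15 s
        assert elevated > 0

    def test_elevated_baseline_is_rms_over_activity(self, params):
        x = np.full(256 * 30, 0.01)
        x[256 * 5:256 * 25] = 0.04
        tonic, elevated = score_tonic(0.0, [ev(5.0, 25.0)],
                                      make_channel(x), params)
        assert tonic
        assert elevated == pytest.approx(0.04, rel=1e-6)


class TestRescore:
    def _plateau_channel(self, rng, b0=0.01, plateau=4.0, bursts=()):
        """One 30 s epoch of tonic plateau with optional extra bursts."""
        n = 256 * 30
        x = band_noise(rng, n, rms=b0) * plateau
        for s, d, ratio in bursts:
            i0, i1 = round(s * 256), round((s + d) * 256)
            x[i0:i1] *= ratio
        return make_channel(x)

    def test_plain_plateau_yields_no_phasic(self, params, rng):
        ch = self._plateau_channel(rng)
        elevated = float(np.sqrt(np.mean(ch.samples ** 2)))
        out = rescore_phasic_in_tonic(ch, 0.0, np.array([[0.0, 30.0]]),
                                      elevated, params)
        assert out == []

    def test_burst_at_3x_plateau_survives_1p5x_does_not(self, params):
        # 32 Hz carrier: the 30 ms window RMS is exactly the level of each
        # plateau, so the two-level geometry is analytic, not statistical
        t = np.arange(256 * 30) / 256.0
        x = 0.04 * np.sqrt(2) * np.sin(2 * np.pi * 32 * t)
        for s, ratio in ((10.0, 3.0), (20.0, 1.5)):
            x[round(s * 256):round((s + 1.0) * 256)] *= ratio
        ch = make_channel(x)
        tonic, elevated = score_tonic(0.0, [ev(0.0, 30.0)], ch, params)
        assert tonic
        out = rescore_phasic_in_tonic(ch, 0.0, np.array([[0.0, 30.0]]),
                                      elevated, params)
        assert len(out) == 1
        assert out[0].category is Category.PHASIC
        assert out[0].start == pytest.approx(10.0, abs=0.05)
        assert out[0].end == pytest.approx(11.0, abs=0.05)


class TestMiniEpochs:
    def _grid(self, tonic=False, valid=True):
        epochs = pd.DataFrame({"valid": [valid], "tonic": [tonic]},
                              index=pd.Index([0.0], name="onset_s"))
        minis = pd.DataFrame({
            "epoch_onset": [0.0] * 10, "valid": [valid] * 10,
        }, index=pd.Index(np.arange(10) * 3.0, name="onset_s"))
        return epochs, minis

    def test_one_second_event_marks_its_mini(self, params):
        epochs, minis = self._grid()
        out = score_mini_epochs(epochs, minis, [ev(12.5, 13.5)], {}, params)
        assert list(out.index[out["phasic"]]) == [12.0]
        assert list(out.index[out["any"]]) == [12.0]

    def test_seven_second_event_any_not_phasic(self, params):
        epochs, minis = self._grid()
        out = score_mini_epochs(
            epochs, minis, [ev(7.0, 14.0, Category.INTERMEDIATE)], {},
            params)
        assert not out["phasic"].any()
        assert list(out.index[out["any"]]) == [6.0, 9.0, 12.0]

    def test_tonic_epoch_all_any_none_phasic(self, params):
        epochs, minis = self._grid(tonic=True)
        out = score_mini_epochs(epochs, minis,
                                [ev(0.0, 30.0, Category.TONIC)],
                                {0.0: []}, params)
        assert out["any"].all()
        assert not out["phasic"].any()

    def test_event_longer_than_15s_in_nontonic_epoch_counts_nothing(
            self, params):
        epochs, minis = self._grid()
        out = score_mini_epochs(epochs, minis,
                                [ev(2.0, 18.5, Category.TONIC)], {}, params)
        assert not out["any"].any() and not out["phasic"].any()

    def test_invalid_minis_never_flagged(self, params):
        epochs, minis = self._grid()
        minis.loc[12.0, "valid"] = False
        out = score_mini_epochs(epochs, minis, [ev(12.5, 13.5)], {}, params)
        assert not out.loc[12.0, "phasic"] and not out.loc[12.0, "any"]


@pytest.fixture(scope="module")
def pipeline_spec():
    return sf.burst_recovery_spec(5, 3, 1, 1)


class TestPipelineInvariants:
    @pytest.fixture
    def spec(self, pipeline_spec):
        return pipeline_spec

    def test_scale_invariance(self, params, spec):
        rec = sf.synthesize_recording(spec)
        res1 = score_recording(rec, spec.hypnogram(), params=params)
        for ch in rec.channels:
            ch.samples = ch.samples * 37.5
        res2 = score_recording(rec, spec.hypnogram(), params=params)
        for role in res1.channels:
            t1, t2 = res1.channels[role].table, res2.channels[role].table
            pd.testing.assert_series_equal(t1.epochs["tonic"],
                                           t2.epochs["tonic"])
            pd.testing.assert_series_equal(t1.minis["phasic"],
                                           t2.minis["phasic"])
            pd.testing.assert_series_equal(t1.minis["any"],
                                           t2.minis["any"])
            assert [(e.start, e.end) for e in t1.events] == \
                [(e.start, e.end) for e in t2.events]

    def test_phasic_subset_of_any(self, params, spec):
        rec = sf.synthesize_recording(spec)
        res = score_recording(rec, spec.hypnogram(), params=params)
        for score in res.channels.values():
            mi = score.table.minis
            assert not (mi["phasic"] & ~mi["any"]).any()

    def test_determinism(self, params, spec):
        res1 = score_recording(sf.synthesize_recording(spec),
                               spec.hypnogram(), params=params)
        res2 = score_recording(sf.synthesize_recording(spec),
                               spec.hypnogram(), params=params)
        for role in res1.channels:
            e1 = res1.channels[role].events
            e2 = res2.channels[role].events
            assert [(e.start, e.end, e.category) for e in e1] == \
                [(e.start, e.end, e.category) for e in e2]


def test_full_chain_matches_bruteforce_on_short_signals(params, rng):
    """Windowing + thresholding + run/gap analysis vs the literal rules."""
    for _ in range(40):
        dur = float(rng.uniform(2.0, 30.0))
        n = round(dur * 256)
        x = band_noise(rng, n, rms=1.0)
        for _ in range(rng.integers(0, 4)):
            s = rng.uniform(0, dur - 0.5)
            d = rng.uniform(0.05, 3.0)
            i0, i1 = round(s * 256), min(n, round((s + d) * 256))
            x[i0:i1] *= rng.uniform(1.5, 4.0)
        baseline = float(rng.uniform(0.8, 1.2))
        track = compute_rms_track(make_channel(x), 0.0, dur, params)
        flags = detect_activity_bouts(track, baseline, params)
        got = merge_into_events(flags, params)
        want = _oracle.detect_events(x, 256, baseline)
        assert np.allclose(got, np.array(want).reshape(-1, 2), atol=1e-9)
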