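import numpy as np
import pytest

from atonia import Role, estimate_baseline, propagate_baseline
from atonia.baseline_estimation import (BaselineSource,
                                        ChannelDiscardedWarning,
                                        assign_baselines)
from atonia.rem_segmentation import ArtefactMask, RemSegment

import _oracle
from conftest import band_noise, make_channel


def mask_for(segments, intervals=()):
    return ArtefactMask(role=Role.MENTALIS, segments=list(segments),
                        intervals=np.array(intervals, dtype=float)
                        .reshape(-1, 2))


PERIOD = RemSegment(0.0, 180.0, True)


class TestEstimate:
    def test_stationary_noise_within_10pct(self, params, rng):
        ch = make_channel(band_noise(rng, 256 * 180, rms=0.02))
        amp, source = estimate_baseline(ch, PERIOD, mask_for([PERIOD]),
                                        params)
        assert source is BaselineSource.WINDOW30
        assert amp == pytest.approx(0.02, rel=0.10)

    def test_minimum_window_selected(self, params, rng):
        x = band_noise(rng, 256 * 180, rms=0.05)
        x[256 * 90:] = band_noise(rng, 256 * 90, rms=0.02)
        amp, _ = estimate_baseline(make_channel(x), PERIOD,
                                   mask_for([PERIOD]), params)
        assert amp < 0.03

    def test_minimality_against_window_enumeration(self, params, rng):
        seg = RemSegment(0.0, 160.0, True)
        mask = mask_for([seg], [(75.0, 85.0)])
        x = band_noise(rng, 256 * 160, rms=0.03)
        ch = make_channel(x)
        amp, source = estimate_baseline(ch, seg, mask, params)
        assert source is BaselineSource.WINDOW30
        starts = _oracle.enumerate_clean_windows(
            mask.free_runs(seg), params.baseline_window, params.rms_step)
        rms = [np.sqrt(np.mean(x[round(t * 256):round(t * 256) +
                                 int(30 * 256)] ** 2)) for t in starts]
        assert amp == pytest.approx(min(rms), abs=1e-12)
        assert all(amp <= r + 1e-12 for r in rms)

    def test_fallback_to_15s_window_exactly_when_no_30s_run(self, params,
                                                            rng):
        x = band_noise(rng, 256 * 160, rms=0.03)
        ch = make_channel(x)
        seg = RemSegment(0.0, 160.0, True)
        # central artefact leaving two 80 s runs: 30 s windows exist
        amp, source = estimate_baseline(ch, seg, mask_for([seg],
                                                          [(80.0, 80.5)]),
                                        params)
        assert source is BaselineSource.WINDOW30
        # comb of artefacts leaving only 20 s runs: fallback fires
        comb = [(20.0 * k, 20.0 * k + 0.5) for k in range(1, 8)]
        mask = mask_for([seg], comb)
        assert _oracle.enumerate_clean_windows(mask.free_runs(seg),
                                               30.0) == []
        assert _oracle.enumerate_clean_windows(mask.free_runs(seg),
                                               15.0) != []
        amp, source = estimate_baseline(ch, seg, mask, params)
        assert source is BaselineSource.WINDOW15
        assert amp == pytest.approx(0.03, rel=0.15)

    def test_unavailable_when_only_short_runs(self, params, rng):
        x = band_noise(rng, 256 * 160, rms=0.03)
        seg = RemSegment(0.0, 160.0, True)
        comb = [(10.0 * k, 10.0 * k + 0.5) for k in range(1, 16)]
        amp, source = estimate_baseline(make_channel(x), seg,
                                        mask_for([seg], comb), params)
        assert source is BaselineSource.UNAVAILABLE
        assert np.isnan(amp)

    def test_scale_equivariance(self, params, rng):
        x = band_noise(rng, 256 * 180, rms=0.02)
        a1, _ = estimate_baseline(make_channel(x), PERIOD,
                                  mask_for([PERIOD]), params)
        a2, _ = estimate_baseline(make_channel(3.5 * x), PERIOD,
                                  mask_for([PERIOD]), params)
        assert a2 == pytest.approx(3.5 * a1, rel=1e-12)


class TestPropagate:
    P1 = RemSegment(0.0, 180.0, True)
    P2 = RemSegment(400.0, 580.0, True)
    P3 = RemSegment(800.0, 980.0, True)

    def test_inherit_previous(self):
        out = propagate_baseline(
            [self.P1, self.P2],
            [(0.02, BaselineSource.WINDOW30),
             (float("nan"), BaselineSource.UNAVAILABLE)])
        assert out.amplitudes[1] == 0.02
        assert out.sources[1] is BaselineSource.INHERITED_PREV

    def test_inherit_next_when_no_previous(self):
        out = propagate_baseline(
            [self.P1, self.P2],
            [(float("nan"), BaselineSource.UNAVAILABLE),
             (0.03, BaselineSource.WINDOW30)])
        assert out.amplitudes[0] == 0.03
        assert out.sources[0] is BaselineSource.INHERITED_NEXT

    def test_transitive_inheritance_prefers_previous(self):
        out = propagate_baseline(
            [self.P1, self.P2, self.P3],
            [(0.02, BaselineSource.WINDOW30),
             (float("nan"), BaselineSource.UNAVAILABLE),
             (float("nan"), BaselineSource.UNAVAILABLE)])
        assert out.amplitudes[1] == out.amplitudes[2] == 0.02

    def test_bout_takes_nearest_period_tie_to_earlier(self):
        bout = RemSegment(460.0, 520.0, False)     # midpoint 490
        p1 = RemSegment(0.0, 180.0, True)          # midpoint 90
        p2 = RemSegment(800.0, 980.0, True)        # midpoint 890, tie
        out = propagate_baseline(
            [p1, bout, p2],
            [(0.02, BaselineSource.WINDOW30),
             (float("nan"), BaselineSource.UNAVAILABLE),
             (0.03, BaselineSource.WINDOW30)])
        assert out.amplitudes[1] == 0.02
        assert out.sources[1] is BaselineSource.NEAREST_SEGMENT

    def test_bout_nearest_period_by_midpoint(self):
        bout = RemSegment(700.0, 760.0, False)     # midpoint 730 -> P2
        out = propagate_baseline(
            [self.P1, bout, self.P3],
            [(0.02, BaselineSource.WINDOW30),
             (float("nan"), BaselineSource.UNAVAILABLE),
             (0.03, BaselineSource.WINDOW30)])
        assert out.amplitudes[1] == 0.03

    def test_discard_warning_when_nothing_measured(self):
        with pytest.warns(ChannelDiscardedWarning):
            out = propagate_baseline(
                [self.P1], [(float("nan"), BaselineSource.UNAVAILABLE)],
                role=Role.FDS_LEFT)
        assert not out.usable


def test_assign_baselines_consistency_grows_with_length(params, rng):
    """On i.i.d.-style noise the estimate approaches the true RMS."""
    errs = []
    for minutes in (3, 12):
        seg = RemSegment(0.0, 60.0 * minutes, True)
        x = band_noise(rng, int(256 * seg.end), rms=0.02)
        out = assign_baselines(make_channel(x), [seg], mask_for([seg]),
                               params)
        errs.append(abs(out.amplitudes[0] - 0.02))
    assert errs[0] < 0.002 and errs[1] < 0.002
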