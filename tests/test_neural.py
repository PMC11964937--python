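"""Calcium metrics: baseline, transients, tuning, place fields, splitters."""

import numpy as np
import pytest

from osmlab import neural
from osmlab.neural import (CalciumSession, NeuralError, classify_cells,
                           detect_place_fields, detect_transients,
                           field_shift_analysis, preprocess, spatial_dispersion,
                           splitter_score, tuning_curve)


def toy_session(F, position=None, speed=None, licks=None, frame_rate=10.0):
    n = F.shape[1]
    position = np.linspace(0, 229.9, n) if position is None else position
    speed = np.full(n, 20.0) if speed is None else speed
    licks = np.zeros(n, dtype=bool) if licks is None else licks
    licks = licks.copy()
    # one lick inside R1 keeps the single trial "active"
    licks[np.argmin(np.abs(position - 140))] = True
    return CalciumSession(F=F, frame_rate=frame_rate, position=position,
                          speed=speed, licks=licks,
                          trial_id=np.zeros(n, dtype=int),
                          trial_types={0: "near"})


class TestPreprocess:
    def test_constant_trace_flat_dff_no_transients(self):
        sess = toy_session(np.full((1, 600), 50.0))
        dff, transients = preprocess(sess)
        np.testing.assert_allclose(dff.dff, 0.0, atol=1e-12)
        assert transients.intervals[0] == []
        assert dff.sigma_floored[0]

    def test_planted_transient_detected_with_onset_accuracy(self, rng):
        n = 800
        F = 100.0 + rng.normal(0, 0.5, (1, n))
        onset = 400
        F[0, onset:onset + 12] += 100.0 * np.exp(-np.arange(12) / 4)
        sess = toy_session(F)
        dff, transients = preprocess(sess)
        assert len(transients.intervals[0]) == 1
        got_onset, got_end = transients.intervals[0][0]
        assert abs(got_onset - onset) <= 1

    def test_slow_drift_tracked_by_baseline(self, rng):
        n = 1200
        drift = 80 + 8 * np.sin(np.linspace(0, 2 * np.pi, n))
        F = drift[None, :] + rng.normal(0, 0.3, (1, n))
        sess = toy_session(F)
        dff, transients = preprocess(sess)
        # baseline follows the drift, so dff stays near zero throughout
        assert np.abs(dff.dff).max() < 0.15
        assert np.corrcoef(dff.F0[0], drift)[0, 1] > 0.95

    def test_transient_rule_5sigma_onset_1sigma_offset(self):
        dff = np.zeros((1, 100))
        dff[0, 50:56] = [6.0, 5.0, 3.0, 2.0, 1.5, 0.5]
        out = detect_transients(dff, np.array([1.0]))
        assert out.intervals[0] == [(50, 55)]


class TestTuningCurve:
    def test_uniform_dff_gives_flat_curve(self):
        sess = toy_session(np.full((1, 460), 100.0))
        curve = tuning_curve(np.ones((1, 460)), sess, "near")
        occupied = curve.occupancy > 0
        np.testing.assert_allclose(curve.curves[0, occupied], 1.0)

    def test_planted_bump_peak_bin(self, rng):
        n = 460
        pos = np.linspace(0, 229.9, n)
        dff = np.exp(-0.5 * ((pos - 120.0) / 8) ** 2)[None, :]
        sess = toy_session(np.full((1, n), 100.0), position=pos)
        curve = tuning_curve(dff, sess, "near")
        peak_bin = np.argmax(curve.curves[0])
        lo, hi = curve.bin_edges[peak_bin], curve.bin_edges[peak_bin + 1]
        assert lo <= 120.0 < hi

    def test_stationary_frames_excluded(self, rng):
        n = 460
        pos = np.linspace(0, 229.9, n)
        dff = rng.normal(0, 0.1, (1, n))
        sess = toy_session(np.full((1, n), 100.0), position=pos)
        base = tuning_curve(dff, sess, "near").curves
        # appending stationary frames with wild dff changes nothing
        pos2 = np.concatenate([pos, np.full(100, 50.0)])
        dff2 = np.concatenate([dff, np.full((1, 100), 99.0)], axis=1)
        speed2 = np.concatenate([np.full(n, 20.0), np.zeros(100)])
        sess2 = toy_session(np.full((1, n + 100), 100.0), position=pos2,
                            speed=speed2)
        again = tuning_curve(dff2, sess2, "near").curves
        np.testing.assert_allclose(base, again)

    def test_no_qualifying_trials_errors(self):
        sess = toy_session(np.full((1, 100), 100.0))
        with pytest.raises(NeuralError):
            tuning_curve(np.ones((1, 100)), sess, "far")


class TestSpatialDispersion:
    def test_single_bin_zero_bits(self):
        curve = np.zeros(46)
        curve[10] = 3.0
        assert spatial_dispersion(curve) == 0.0

    def test_uniform_over_46_bins(self):
        assert spatial_dispersion(np.ones(46)) == pytest.approx(np.log2(46))

    def test_two_equal_bins_one_bit(self):
        curve = np.zeros(46)
        curve[[3, 30]] = 1.0
        assert spatial_dispersion(curve) == pytest.approx(1.0)

    def test_bounded_by_log2_nbins(self, rng):
        for _ in range(10):
            curve = rng.random(46)
            assert spatial_dispersion(curve) <= np.log2(46) + 1e-12

    def test_all_zero_errors(self):
        with pytest.raises(NeuralError):
            spatial_dispersion(np.zeros(10))


class TestSplitterScore:
    def test_identical_curves_place(self):
        curve = np.exp(-0.5 * ((np.arange(46) - 20) / 3.0) ** 2)
        s = splitter_score(curve, curve)
        assert s.r == pytest.approx(1.0)
        assert s.D == pytest.approx(0.0)
        assert s.category == "place"

    def test_amplitude_half_gives_D_half(self):
        curve = np.exp(-0.5 * ((np.arange(46) - 20) / 3.0) ** 2)
        s = splitter_score(2 * curve, curve)
        assert s.D == pytest.approx(0.5)
        assert s.category == "splitter"

    def test_remapping_splitter(self):
        bins = np.arange(46)
        a = np.exp(-0.5 * ((bins - 10) / 2.0) ** 2)
        b = np.exp(-0.5 * ((bins - 35) / 2.0) ** 2)
        s = splitter_score(a, b)
        assert s.D == pytest.approx(0.0, abs=1e-9)
        assert s.r < 0.2
        assert s.category == "remapping_splitter"

    def test_silent_cell_excluded(self):
        s = splitter_score(np.zeros(46), np.zeros(46))
        assert s.excluded

    def test_category_partition_exhaustive(self, rng):
        cats = set()
        for _ in range(200):
            a, b = rng.random(46), rng.random(46)
            s = splitter_score(a, b)
            assert s.category in ("place", "splitter", "remapping_splitter")
            assert 0.0 <= s.D <= 1.0
            cats.add(s.category)
        assert len(cats) >= 2


class TestPlaceFields:
    def _session_with_field(self, rng, center=100.0, width=15.0, n_trials=20,
                            snr=8.0, tuned=True):
        """Laps over the track with a planted field; returns session+dff."""
        frames_per_lap = 115
        n = frames_per_lap * n_trials
        pos = np.tile(np.linspace(0, 229.9, frames_per_lap), n_trials)
        F = 100.0 + rng.normal(0, 0.5, (1, n))
        if tuned:
            in_field = np.abs(pos - center) < width / 2
            events = in_field & (rng.random(n) < 0.5)
            F[0, events] += snr * 10.0
        licks = np.zeros(n, dtype=bool)
        licks[np.argmin(np.abs(pos - 140))] = True
        tid = np.repeat(np.arange(n_trials), frames_per_lap)
        sess = CalciumSession(F=F, frame_rate=10.0, position=pos,
                              speed=np.full(n, 20.0), licks=np.ones(n, dtype=bool),
                              trial_id=tid,
                              trial_types={i: "near" for i in range(n_trials)})
        return sess

    def test_planted_field_detected_and_significant(self, rng):
        sess = self._session_with_field(rng, center=100, width=30)
        dff, transients = preprocess(sess)
        out = detect_place_fields(dff.dff[0], transients.mask[0], sess,
                                  n_shuffles=200, seed=0)
        assert out.significant
        assert any(lo <= 100 <= hi for lo, hi in out.fields)

    def test_narrow_field_rejected_by_width_rule(self, rng):
        sess = self._session_with_field(rng, center=100, width=6)
        dff, transients = preprocess(sess)
        out = detect_place_fields(dff.dff[0], transients.mask[0], sess,
                                  n_shuffles=50, seed=0)
        assert not any(hi - lo < 15 for lo, hi in out.fields)

    def test_session_shorter_than_block_errors(self, rng):
        sess = toy_session(np.full((1, 50), 100.0))
        with pytest.raises(NeuralError):
            detect_place_fields(np.zeros(50), np.zeros(50, dtype=bool), sess,
                                n_shuffles=10, seed=0)


class TestFieldShift:
    def test_identity_line_and_exclusions(self):
        bins = np.arange(46)
        a = np.exp(-0.5 * ((bins - 8) / 2.0) ** 2)[None, :]
        out = field_shift_analysis(np.vstack([a, a * 0]), np.vstack([a, a * 0]))
        assert out["n_excluded"] == 1
        assert out["pairs"].shape == (1, 2)
        assert out["pairs"][0, 0] == out["pairs"][0, 1]

    def test_empty_overlap(self):
        z = np.zeros((2, 46))
        out = field_shift_analysis(z, z)
        assert out["pairs"].shape == (0, 2)
        assert out["n_excluded"] == 2


class TestClassify:
    def test_weakly_active_cells_excluded(self, rng):
        flat = rng.normal(0, 0.01, (3, 46)) + 0.02      # no real activity
        traces = rng.normal(0, 0.05, (3, 500))          # noisy quiet traces
        scores, fractions = classify_cells(flat, flat, activity_sd=2.0,
                                           traces=traces)
        assert all(s.excluded for s in scores)
        assert np.isnan(fractions["place"])
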