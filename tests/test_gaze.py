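"""Gaze classification: velocity, translation correction, thresholds, events."""

import numpy as np
import pytest

from saccerp.gaze import (
    FIXATION,
    GAP,
    SACCADE,
    GazeEvent,
    GazeTrace,
    VelocitySeries,
    adaptive_thresholds,
    angles_to_vec,
    angular_velocity,
    classify_events,
    correct_translation,
    detect_gaze_events,
    great_circle_deg,
    saccade_amplitude,
)


def _trace(az, el=None, rate=90.0, **kw):
    az = np.asarray(az, dtype=float)
    el = np.zeros_like(az) if el is None else np.asarray(el, dtype=float)
    t = np.arange(len(az)) / rate
    return GazeTrace(time=t, az=az, el=el, rate=rate, **kw)


class TestAngularVelocity:
    def test_constant_direction_is_zero(self):
        vel = angular_velocity(_trace(np.full(50, 7.0), np.full(50, -3.0)))
        assert np.all(vel.omega == 0.0)

    def test_constant_rotation_rate(self):
        # 1 degree per sample at 90 Hz -> 90 deg/s at interior samples
        vel = angular_velocity(_trace(np.arange(50, dtype=float)))
        assert np.allclose(vel.omega, 90.0, rtol=1e-6)

    def test_nan_propagates_only_through_stencil(self):
        az = np.zeros(20)
        az[10] = np.nan
        vel = angular_velocity(_trace(az))
        # vel index i corresponds to trace sample i+1; stencil is {i, i+2}
        nan_at = np.flatnonzero(np.isnan(vel.omega)) + 1
        assert set(nan_at) == {9, 11}

    def test_non_monotonic_time_fails(self):
        t = np.array([0.0, 0.1, 0.05])
        with pytest.raises(ValueError, match="increasing"):
            GazeTrace(time=t, az=np.zeros(3), el=np.zeros(3), rate=90.0)

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            angular_velocity(_trace([0.0, 1.0]))


class TestCorrectTranslation:
    def test_static_head_is_identity(self):
        n = 40
        tr = _trace(
            np.linspace(0, 10, 40),
            head_pos=np.zeros((n, 3)),
            gaze_dist=np.full(n, 5.0),
        )
        out = correct_translation(tr)
        assert np.allclose(out.az, tr.az, atol=1e-9)
        assert np.allclose(out.el, tr.el, atol=1e-9)

    def test_locked_gaze_geometry_oracle(self):
        # eye locked on a world point at distance d while the head moves on a
        # straight line perpendicular to the line of sight at speed v:
        # uncorrected angular velocity = v/d (small-angle), corrected ~ 0
        rate, v, d = 90.0, 0.5, 4.0
        n = 90
        t = np.arange(n) / rate
        head = np.stack([v * t, np.zeros(n), np.zeros(n)], axis=1)
        target = np.array([0.0, 0.0, d])
        rel = target - head
        dist = np.linalg.norm(rel, axis=1)
        az = np.degrees(np.arctan2(rel[:, 0], rel[:, 2]))
        el = np.zeros(n)
        tr = GazeTrace(time=t, az=az, el=el, rate=rate, head_pos=head, gaze_dist=dist)
        raw = angular_velocity(tr)
        predicted = np.degrees(v / d)  # at t=0 the sight line is perpendicular
        assert raw.omega[0] == pytest.approx(predicted, rel=0.05)
        cor = angular_velocity(correct_translation(tr))
        assert np.nanmax(cor.omega) < 1e-6 * predicted

    def test_correction_lowers_fixation_velocities(self, moving_session):
        trace = moving_session.trace
        raw = angular_velocity(trace)
        cor = angular_velocity(correct_translation(trace))
        fix = moving_session.truth.fixations
        inside = np.zeros(len(raw.time), bool)
        for r in fix.itertuples():
            a, b = np.searchsorted(raw.time, [r.onset_s + 0.03, r.offset_s - 0.03])
            inside[a:b] = True
        assert np.median(cor.omega[inside]) < np.median(raw.omega[inside])

    def test_missing_channels_named(self):
        tr = _trace(np.zeros(10))
        with pytest.raises(ValueError, match="head_pos"):
            correct_translation(tr)
        tr2 = _trace(np.zeros(10), head_pos=np.zeros((10, 3)))
        with pytest.raises(ValueError, match="gaze_dist"):
            correct_translation(tr2)


class TestAdaptiveThresholds:
    def _vel(self, omega, rate=90.0):
        t = np.arange(len(omega)) / rate
        return VelocitySeries(time=t, omega=np.asarray(omega, float))

    def test_constant_series_threshold_equals_value(self):
        sched = adaptive_thresholds(self._vel(np.full(900, 10.0)), interval_len=10.0)
        assert np.allclose(sched.thresholds, 10.0)

    def test_two_value_series_matches_enumeration(self):
        omega = np.tile([10.0, 20.0], 450)
        sched = adaptive_thresholds(self._vel(omega), interval_len=10.0, lam=5.0)
        med = np.median(omega)
        rsd = 1.4826 * np.median(np.abs(omega - med))
        assert np.allclose(sched.thresholds, med + 5.0 * rsd)

    def test_intervals_with_different_floors(self, rng):
        # 1801 samples at 90 Hz span exactly 20 s -> two 10-s intervals
        omega = np.concatenate(
            [1.0 + 0.1 * rng.standard_normal(900), 50.0 + 5.0 * rng.standard_normal(901)]
        )
        sched = adaptive_thresholds(self._vel(np.abs(omega)), interval_len=10.0)
        assert len(sched.thresholds) == 2
        assert sched.thresholds[1] > sched.thresholds[0]

    def test_all_nan_interval_inherits(self, rng):
        omega = np.abs(rng.standard_normal(1801)) + 1.0
        omega[900:] = np.nan
        sched = adaptive_thresholds(self._vel(omega), interval_len=10.0)
        assert len(sched.thresholds) == 2
        assert sched.thresholds[1] == sched.thresholds[0]

    def test_validation(self):
        v = self._vel(np.ones(200))
        with pytest.raises(ValueError):
            adaptive_thresholds(v, interval_len=0.5)
        with pytest.raises(ValueError):
            adaptive_thresholds(v, lam=0.0)


class TestClassifyEvents:
    def _series(self, omega, rate=90.0):
        t = np.arange(len(omega)) / rate
        return VelocitySeries(time=t, omega=np.asarray(omega, float))

    def test_silent_series_is_single_fixation(self):
        vel = self._series(np.zeros(900))
        sched = adaptive_thresholds(vel)
        events = classify_events(vel, sched)
        assert len(events) == 1
        assert events[0].kind == FIXATION
        assert events[0].onset == vel.time[0]
        assert events[0].offset == vel.time[-1]

    def test_single_sample_blip_absorbed(self):
        from saccerp.gaze import ThresholdSchedule

        omega = np.ones(300)
        omega[150] = 500.0  # 1 sample at 90 Hz = 11 ms < min_sacc 22 ms
        vel = self._series(omega)
        sched = ThresholdSchedule(
            edges=np.array([vel.time[0], vel.time[-1] + 1]), thresholds=np.array([100.0])
        )
        events = classify_events(vel, sched, min_sacc=0.022)
        assert all(e.kind == FIXATION for e in events)
        assert len(events) == 1

    def test_alternation_and_coverage(self, clean_session):
        vel = angular_velocity(clean_session.trace)
        sched = adaptive_thresholds(vel)
        events = classify_events(vel, sched)
        kinds = [e.kind for e in events if e.kind != GAP]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        # coverage: events tile the velocity span exactly
        assert events[0].onset == vel.time[0]
        assert events[-1].offset == vel.time[-1]
        for a, b in zip(events, events[1:]):
            assert a.offset == pytest.approx(b.onset, abs=1e-12)

    def test_long_dropout_becomes_gap(self):
        omega = np.ones(300)
        omega[100:130] = np.nan  # 330 ms dropout
        vel = self._series(omega)
        sched = adaptive_thresholds(vel)
        events = classify_events(vel, sched)
        gaps = [e for e in events if e.kind == GAP]
        assert len(gaps) == 1
        assert gaps[0].duration > 0.1

    def test_empty_series(self):
        from saccerp.gaze import ThresholdSchedule

        sched = ThresholdSchedule(edges=np.array([0.0, 1.0]), thresholds=np.array([1.0]))
        assert classify_events(VelocitySeries(np.array([]), np.array([])), sched) == []

    def test_recovery_on_clean_session(self, clean_session):
        events = detect_gaze_events(clean_session.trace, correct=False)
        det = np.array([e.onset for e in events if e.kind == SACCADE])
        gt = clean_session.truth.saccades
        big = gt[gt["amplitude_deg"] >= 1.0]
        tol = 1.0 / 90 + 1e-9
        errs = np.array([np.min(np.abs(det - o)) for o in big["onset_s"]])
        assert np.mean(errs <= tol) >= 0.98

    def test_correction_restores_hit_rate(self, moving_session):
        gt = moving_session.truth.saccades
        big = gt[gt["amplitude_deg"] >= 1.0]
        tol = 1.0 / 90 + 1e-9

        def rate(correct):
            ev = detect_gaze_events(moving_session.trace, correct=correct)
            det = np.array([e.onset for e in ev if e.kind == SACCADE])
            return np.mean([np.min(np.abs(det - o)) <= tol for o in big["onset_s"]])

        assert rate(True) > rate(False) + 0.1


class TestSaccadeAmplitude:
    def test_zero_for_equal_directions(self):
        tr = _trace(np.zeros(10))
        ev = GazeEvent(kind=SACCADE, onset=0.0, offset=0.05)
        assert saccade_amplitude(tr, ev) == pytest.approx(0.0, abs=1e-12)

    def test_pure_azimuth_rotation(self):
        az = np.concatenate([np.zeros(5), np.full(5, 10.0)])
        tr = _trace(az)
        ev = GazeEvent(kind=SACCADE, onset=tr.time[4], offset=tr.time[5])
        assert saccade_amplitude(tr, ev) == pytest.approx(10.0, abs=1e-9)

    def test_oblique_step_matches_spherical_law_of_cosines(self):
        az = np.array([0.0, 10.0])
        el = np.array([0.0, 10.0])
        tr = GazeTrace(time=np.array([0.0, 0.05]), az=az, el=el, rate=20.0)
        ev = GazeEvent(kind=SACCADE, onset=0.0, offset=0.05)
        expected = np.degrees(
            np.arccos(
                np.sin(0) * np.sin(np.radians(10))
                + np.cos(0) * np.cos(np.radians(10)) * np.cos(np.radians(10))
            )
        )
        assert saccade_amplitude(tr, ev) == pytest.approx(expected, abs=1e-9)

    def test_event_outside_trace_fails(self):
        tr = _trace(np.zeros(10))
        ev = GazeEvent(kind=SACCADE, onset=5.0, offset=5.1)
        with pytest.raises(ValueError):
            saccade_amplitude(tr, ev)

    def test_fixation_rejected(self):
        tr = _trace(np.zeros(10))
        ev = GazeEvent(kind=FIXATION, onset=0.0, offset=0.05)
        with pytest.raises(ValueError):
            saccade_amplitude(tr, ev)


def test_great_circle_symmetry(rng):
    u = angles_to_vec(rng.uniform(-60, 60, 50), rng.uniform(-30, 30, 50))
    v = angles_to_vec(rng.uniform(-60, 60, 50), rng.uniform(-30, 30, 50))
    assert np.allclose(great_circle_deg(u, v), great_circle_deg(v, u))
    assert np.all(great_circle_deg(u, v) >= 0)
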