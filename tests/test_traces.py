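"""Ramp-intercept event measurement, scission, averaging, calibration."""

import numpy as np
import pytest

from endotrace import traces as ta
from endotrace.containers import IntensityTrace
from endotrace.sim import EventKinetics, generate_event_trace
from endotrace.sim import presets as preset_lib


def trace_from(y, dt=0.05):
    y = np.asarray(y, dtype=float)
    return IntensityTrace(time=np.arange(len(y)) * dt, intensity=y, frame_interval=dt)


class TestCorrectBackground:
    def test_uniform_field_cancels_exactly(self):
        out = ta.correct_background(np.full(10, 25 * 3.0), np.full(10, 3.0), frame_interval=0.05)
        assert np.all(out.intensity == 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ta.correct_background(np.zeros(5), np.zeros(6), frame_interval=0.05)

    def test_planar_background_gradient_removed(self, endocam, trapezoid):
        from endotrace.sim import PlacedEvent, generate_movie
        from endotrace import detection

        ev = PlacedEvent(2.5, 2.5, trapezoid, t_start=3.0)
        movie, _ = generate_movie(
            [ev], None, endocam, (5.0, 5.0), 19.0, seed=4, background_gradient=(40.0, 25.0)
        )
        core, bg = detection.extract_roi_trace(movie, detection.EventROI((24, 24)))
        corrected = ta.correct_background(core, bg, frame_interval=movie.frame_interval)
        baseline = corrected.intensity[: int(2.0 / movie.frame_interval)]
        plateau = trapezoid.peak_molecules * endocam.single_fluorophore_intensity
        assert abs(baseline.mean()) < 0.02 * plateau


class TestFitRamp:
    def test_pure_line_recovered_in_earliest_window(self):
        dt = 0.05
        y = 100.0 * np.arange(200) * dt
        fit = ta.fit_ramp(trace_from(y), direction="rising")
        assert fit.slope == pytest.approx(100.0)
        assert fit.window_start == 0  # ties broken by earliest window
        assert fit.t_zero == pytest.approx(0.0, abs=1e-9)

    def test_constant_trace_has_zero_slope(self):
        for direction in ("rising", "falling"):
            assert ta.fit_ramp(trace_from(np.full(100, 5.0)), direction=direction).slope == pytest.approx(
                0.0, abs=1e-12
            )

    def test_noiseless_trapezoid_rise_window_and_gradient(self, quiet_endocam, trapezoid):
        trace, _ = generate_event_trace(trapezoid, quiet_endocam, seed=0)
        fit = ta.fit_ramp(trace, direction="rising")
        true_slope = trapezoid.rise_rate * quiet_endocam.single_fluorophore_intensity
        assert fit.slope == pytest.approx(true_slope, rel=0.01)
        # fitted 60-point window must sit inside the 3.46-s rise phase
        start_t = trace.time[fit.window_start]
        assert 3.0 - 1e-9 <= start_t and start_t + 3.0 <= 3.0 + trapezoid.rise_time + 1e-9

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            ta.fit_ramp(trace_from(np.zeros(30)))


class TestMeasureEvent:
    @pytest.mark.parametrize("rise_rate", [4.5, 6.5, 9.0, 11.0, 13.0, 15.0])
    def test_trapezoid_duration_within_one_frame(self, quiet_endocam, rise_rate):
        # rise times from ~3 s (the fitting window) up to 10 s
        kin = EventKinetics(rise_rate=rise_rate, peak_molecules=45.0, plateau_duration=6.0, fall_rate=14.0)
        trace, truth = generate_event_trace(kin, quiet_endocam, pre_roll=4.0, post_roll=4.0, seed=0)
        m = ta.measure_event(trace)
        assert m.t_dur == pytest.approx(truth.t_end - truth.t_start, abs=quiet_endocam.frame_interval)
        assert m.t_start == pytest.approx(truth.t_start, abs=quiet_endocam.frame_interval)

    @pytest.mark.parametrize("rise_rate", [22.5, 45.0])
    def test_short_rise_bias_is_bounded_overestimate(self, quiet_endocam, rise_rate):
        # when the ramp is shorter than the 60-point window the fitted
        # line spans the corners and T_dur is overestimated by a bounded
        # amount (documented limitation of the fixed-window method)
        kin = EventKinetics(rise_rate=rise_rate, peak_molecules=45.0, plateau_duration=6.0, fall_rate=14.0)
        trace, truth = generate_event_trace(kin, quiet_endocam, pre_roll=4.0, post_roll=4.0, seed=0)
        m = ta.measure_event(trace)
        err = m.t_dur - (truth.t_end - truth.t_start)
        assert 0.0 <= err < 0.7

    def test_timing_invariant_to_intensity_rescaling(self, quiet_endocam, trapezoid):
        trace, _ = generate_event_trace(trapezoid, quiet_endocam, seed=0)
        scaled = IntensityTrace(trace.time, trace.intensity * 7.3, trace.frame_interval)
        m0, m1 = ta.measure_event(trace), ta.measure_event(scaled)
        assert m1.t_dur == pytest.approx(m0.t_dur, abs=1e-9)
        assert m1.t_start == pytest.approx(m0.t_start, abs=1e-9)

    def test_flat_trace_is_malformed(self):
        with pytest.raises(ta.MalformedEventError):
            ta.measure_event(trace_from(np.zeros(200)))

    def test_amplitude_window_average(self, quiet_endocam, trapezoid):
        trace, truth = generate_event_trace(trapezoid, quiet_endocam, seed=0)
        m = ta.measure_event(trace)
        # [T_start+5, T_start+8) lies in the plateau for this shape
        assert m.a_av == pytest.approx(45.0 * quiet_endocam.single_fluorophore_intensity, rel=0.01)
        assert "amplitude-window-truncated" not in m.flags

    def test_truncated_amplitude_window_flagged(self, quiet_endocam):
        # short event: the trace ends before T_start + 8 s
        kin = EventKinetics(rise_rate=15.0, peak_molecules=45.0, plateau_duration=0.5, fall_rate=45.0)
        trace, _ = generate_event_trace(kin, quiet_endocam, pre_roll=3.0, post_roll=1.5, seed=0)
        m = ta.measure_event(trace)
        assert "amplitude-window-truncated" in m.flags


class TestDetectScission:
    def test_step_trace_gives_step_time(self):
        y = np.concatenate([np.full(100, 1000.0), np.zeros(60)])
        t = ta.detect_scission(trace_from(y), plateau=1000.0)
        assert t == pytest.approx(100 * 0.05)

    def test_gradual_myo1_fall_is_absent(self, quiet_endocam):
        kin = preset_lib.event_kinetics_preset("myo1")
        trace, _ = generate_event_trace(kin, quiet_endocam, seed=0)
        plateau = kin.peak_molecules * quiet_endocam.single_fluorophore_intensity
        assert ta.detect_scission(trace, plateau=plateau) is None

    def test_cam2_scission_within_one_frame_of_truth(self, quiet_endocam):
        kin = preset_lib.event_kinetics_preset("cam2")
        trace, truth = generate_event_trace(kin, quiet_endocam, seed=0)
        plateau = kin.peak_molecules * quiet_endocam.single_fluorophore_intensity
        t = ta.detect_scission(trace, plateau=plateau)
        assert t == pytest.approx(truth.t_scis, abs=trace.frame_interval)

    def test_invalid_plateau_rejected(self):
        with pytest.raises(ValueError):
            ta.detect_scission(trace_from(np.zeros(10)), plateau=0.0)


class TestSynchronizeAndAverage:
    def test_alignment_identity_for_shifted_copies(self, quiet_endocam, trapezoid):
        t1, _ = generate_event_trace(trapezoid, quiet_endocam, pre_roll=2.0, post_roll=3.0, seed=0)
        t2, _ = generate_event_trace(trapezoid, quiet_endocam, pre_roll=5.0, post_roll=3.0, seed=0)
        m1, m2 = ta.measure_event(t1), ta.measure_event(t2)
        prof = ta.synchronize_and_average([t1, t2], [m1, m2], anchor="T_start")
        both = prof.n == 2
        assert both.sum() > 200
        # where both traces contribute, the average equals trace 1 shifted
        # so its frame-aligned T_start sits at t = 0
        dt = t1.frame_interval
        offset = int(round(m1.t_start / dt))
        idx1 = np.round(prof.time[both] / dt).astype(int) + offset
        np.testing.assert_allclose(prof.mean[both], t1.intensity[idx1], atol=1e-9)

    def test_sem_shrinks_as_sqrt_n(self, rng):
        dt = 0.05
        traces = [trace_from(rng.normal(0, 1.0, 400), dt) for _ in range(40)]
        anchors = [5.0] * 40
        prof = ta.synchronize_and_average(traces, [None] * 40, anchor="external", external_anchors=anchors)
        full = prof.n == 40
        expected = 1.0 / np.sqrt(40)
        assert np.mean(prof.sem[full]) == pytest.approx(expected, rel=0.2)

    def test_missing_anchor_excluded_and_counted(self, quiet_endocam, trapezoid):
        t1, _ = generate_event_trace(trapezoid, quiet_endocam, seed=0)
        traces = [t1, t1, t1]
        m = ta.measure_event(t1)
        prof = ta.synchronize_and_average(traces, [m, None, m], anchor="T_start")
        assert prof.n_excluded == 1
        assert prof.n.max() == 2

    def test_requires_two_traces(self, quiet_endocam, trapezoid):
        t1, _ = generate_event_trace(trapezoid, quiet_endocam, seed=0)
        with pytest.raises(ValueError):
            ta.synchronize_and_average([t1], [ta.measure_event(t1)])


class TestCalibration:
    def test_identity_conversion(self):
        calib = ta.CalibrationModel(single_fluorophore_intensity=52.7, excitation_scale=1.0)
        assert ta.to_molecules(52.7, calib) == pytest.approx(1.0)

    def test_excitation_scale_applied(self):
        calib = ta.CalibrationModel(single_fluorophore_intensity=263.5, excitation_scale=0.2)
        assert ta.to_molecules(2371.5, calib) == pytest.approx(45.0)

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValueError):
            ta.CalibrationModel(single_fluorophore_intensity=-5.0)

    def test_constant_emitters_recovered_exactly(self):
        tracks = [np.full(8, 240.0) for _ in range(25)]
        calib = ta.estimate_single_fluorophore_intensity(tracks)
        assert calib.single_fluorophore_intensity == pytest.approx(240.0)

    def test_too_few_tracks_rejected(self):
        with pytest.raises(ValueError):
            ta.estimate_single_fluorophore_intensity([np.full(8, 240.0)] * 5)

    def test_median_robust_to_double_occupancy(self, rng):
        tracks = [np.full(8, 240.0) + rng.normal(0, 5, 8) for _ in range(40)]
        tracks += [np.full(8, 480.0) for _ in range(5)]  # two molecules co-located
        calib = ta.estimate_single_fluorophore_intensity(tracks)
        assert calib.single_fluorophore_intensity == pytest.approx(240.0, rel=0.05)
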