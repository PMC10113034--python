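import numpy as np
import pytest

from larvatrack.events import (
    EventConfig,
    HCInterval,
    MotionSeries,
    analyse_track,
    classify_runs,
    classify_stepping,
    detect_head_casts,
    detect_steps,
    detect_switches,
    smooth_and_differentiate,
)
from larvatrack.record import TrackRecord
from larvatrack.synth import LarvaKinematicParams, simulate_track, truth_to_track

from conftest import scripted_velocity_track, straight_track


def _series_from_velocity(v, fps=10.0, bl=4.0):
    track = scripted_velocity_track(np.asarray(v), fps=fps, body_length_mm=bl)
    return smooth_and_differentiate(track, EventConfig(smooth_window_s=1e-6), fps)


def _bare_series(n, fps=10.0, **overrides):
    s = MotionSeries(
        fps=fps,
        time_s=np.arange(n) / fps,
        valid=np.ones(n, bool),
        mean_body_length_mm=4.0,
        midpoint_mm=np.zeros((n, 2)),
        midpoint_speed_mm_s=np.zeros(n),
        midpoint_speed_bl_s=np.zeros(n),
        head_forward_velocity_bl_s=np.zeros(n),
        tail_forward_velocity_mm_s=np.zeros(n),
        tail_forward_velocity_bl_s=np.zeros(n),
        hv_angle_deg=np.zeros(n),
        tv_angle_deg=np.zeros(n),
        hv_angular_speed_deg_s=np.zeros(n),
        tv_angular_speed_deg_s=np.zeros(n),
        hv_angular_accel_deg_s2=np.zeros(n),
        tv_angular_accel_deg_s2=np.zeros(n),
        bending_angle_deg=np.zeros(n),
        spine_smooth_mm=np.zeros((n, 12, 2)),
    )
    for k, v in overrides.items():
        setattr(s, k, np.asarray(v, dtype=float))
    return s


class TestSmoothAndDifferentiate:
    def test_tail_forward_velocity_axial_motion(self):
        track = straight_track(speed_mm_s=2.0, fps=10)
        s = smooth_and_differentiate(track)
        assert np.allclose(s.tail_forward_velocity_mm_s[5:-5], 2.0, atol=0.01)

    def test_perpendicular_motion_zero_forward_velocity(self):
        # rigid larva pointing +x, translating +y
        n, fps = 100, 10.0
        tail = np.stack([np.zeros(n), np.arange(n) * 0.2], axis=1)
        offsets = np.linspace(0, 4, 12)
        spine = tail[:, None, :] + np.stack(
            [offsets, np.zeros(12)], axis=1
        )[None, :, :]
        s = smooth_and_differentiate(TrackRecord(0, np.arange(n), spine, fps))
        assert np.allclose(s.tail_forward_velocity_mm_s[5:-5], 0.0, atol=1e-6)

    def test_uniform_rotation_angular_speed(self):
        # head vector rotating clockwise 10 deg/frame at 10 fps -> +100 deg/s
        n, fps = 80, 10.0
        ang = -np.radians(10.0) * np.arange(n)  # clockwise in y-up frame
        spine = np.zeros((n, 12, 2))
        for i in range(12):
            r = i / 11 * 4
            spine[:, i, 0] = r * np.cos(ang)
            spine[:, i, 1] = r * np.sin(ang)
        s = smooth_and_differentiate(
            TrackRecord(0, np.arange(n), spine, fps), EventConfig(smooth_window_s=1e-6)
        )
        assert np.allclose(s.hv_angular_speed_deg_s[3:-3], 100.0, atol=1.0)

    def test_too_short_track_flagged_empty(self):
        track = straight_track(n_frames=2, fps=10)
        s = smooth_and_differentiate(track)
        assert s.empty

    def test_angular_series_unwrapped(self):
        n, fps = 120, 10.0
        ang = np.radians(350.0 / 119) * np.arange(n)  # nearly a full turn
        spine = np.zeros((n, 12, 2))
        for i in range(12):
            r = i / 11 * 4
            spine[:, i, 0] = r * np.cos(ang)
            spine[:, i, 1] = r * np.sin(ang)
        s = smooth_and_differentiate(
            TrackRecord(0, np.arange(n), spine, fps), EventConfig(smooth_window_s=1e-6)
        )
        assert np.abs(np.diff(s.hv_angle_deg)).max() < 90.0


class TestDetectHeadCasts:
    def test_right_hc_detected(self):
        n = 30
        w = np.zeros(n)
        w[10:15] = 40.0  # +40 deg/s for 0.5 s at 10 fps
        s = _bare_series(n, hv_angular_speed_deg_s=w)
        hcs = detect_head_casts(s, [])
        assert len(hcs) == 1
        assert hcs[0].side == "right"
        assert (hcs[0].start_frame, hcs[0].end_frame) == (10, 14)

    def test_tv_discard_rule(self):
        n = 30
        w = np.zeros(n)
        w[10:15] = 40.0
        tv = np.zeros(n)
        tv[12] = 50.0
        s = _bare_series(n, hv_angular_speed_deg_s=w, tv_angular_speed_deg_s=tv)
        assert detect_head_casts(s, []) == []

    def test_below_threshold_no_hc(self):
        s = _bare_series(50, hv_angular_speed_deg_s=np.full(50, 30.0))
        assert detect_head_casts(s, []) == []

    def test_two_steps_inside_discarded(self):
        from larvatrack.events import StepEvent

        n = 30
        w = np.zeros(n)
        w[10:20] = 40.0
        s = _bare_series(n, hv_angular_speed_deg_s=w)
        steps = [StepEvent(12, 1.2, 1.0), StepEvent(18, 1.8, 1.0)]
        assert detect_head_casts(s, steps) == []
        assert len(detect_head_casts(s, steps[:1])) == 1

    def test_left_side_sign(self):
        n = 30
        w = np.zeros(n)
        w[5:9] = -40.0
        s = _bare_series(n, hv_angular_speed_deg_s=w)
        (hc,) = detect_head_casts(s, [])
        assert hc.side == "left"

    def test_hc_angle_is_bending_difference(self):
        n = 30
        w = np.zeros(n)
        w[10:15] = 40.0
        bend = np.linspace(0, 29, n)
        s = _bare_series(n, hv_angular_speed_deg_s=w, bending_angle_deg=bend)
        (hc,) = detect_head_casts(s, [])
        assert hc.hc_angle_deg == pytest.approx(bend[14] - bend[10])


class TestClassifyRuns:
    def test_no_hcs_all_true(self):
        assert classify_runs([], 50, 10).all()

    def test_exclusion_window_arithmetic(self):
        # HC spanning [10, 11] s at 10 fps: frames [85, 125] excluded
        mask = classify_runs([HCInterval(100, 110, "left", 0.0)], 200, 10)
        assert not mask[85:126].any()
        assert mask[:85].all() and mask[126:].all()

    def test_adjacent_hcs_merge_exclusions(self):
        hcs = [HCInterval(50, 55, "left", 0.0), HCInterval(65, 70, "right", 0.0)]
        mask = classify_runs(hcs, 150, 10)
        assert not mask[35:86].any()


class TestDetectSteps:
    def test_sinusoid_crest_count_and_interval(self):
        fps = 10.0
        t = np.arange(0, 10, 1 / fps)
        v = 1.2 * np.abs(np.sin(np.pi * t)) + 0.01  # crests every 1 s
        # closed form: crests at t = 0.5, 1.5, ..., 9.5
        s = _bare_series(len(t), fps=fps, tail_forward_velocity_mm_s=v)
        s.midpoint_mm = np.stack([np.cumsum(v) / fps, np.zeros(len(t))], axis=1)
        s.midpoint_speed_mm_s = v.copy()
        steps, cycles = detect_steps(s)
        assert len(steps) == 10
        assert np.allclose([st.time_s for st in steps], np.arange(10) + 0.5, atol=0.05)
        assert np.allclose([c.interval_s for c in cycles], 1.0, atol=0.01)

    def test_constant_low_velocity_no_steps(self):
        s = _bare_series(100, tail_forward_velocity_mm_s=np.full(100, 0.3))
        steps, _ = detect_steps(s)
        assert steps == []

    def test_below_floor_maxima_discarded(self):
        v = np.zeros(50)
        v[10] = 0.5  # a clear local maximum but below 0.6 mm/s
        v[30] = 0.9
        s = _bare_series(50, tail_forward_velocity_mm_s=v)
        steps, _ = detect_steps(s)
        assert [st.frame for st in steps] == [30]

    def test_plateau_counts_once_at_first_frame(self):
        v = np.full(40, 0.1)
        v[20] = v[21] = 1.5  # two equal adjacent samples
        s = _bare_series(40, tail_forward_velocity_mm_s=v)
        steps, _ = detect_steps(s)
        assert [st.frame for st in steps] == [20]

    def test_run_mask_respected(self):
        v = np.full(50, 0.1)
        v[10] = v[30] = 1.0
        mask = np.ones(50, bool)
        mask[5:15] = False
        s = _bare_series(50, tail_forward_velocity_mm_s=v)
        steps, _ = detect_steps(s, mask)
        assert [st.frame for st in steps] == [30]


class TestClassifyStepping:
    def _cycle_series(self, shape):
        v = np.full(40, 0.1)
        v[10] = v[30] = 1.5
        if shape == "clean":
            v[11:30] = 0.5 + 0.3 * np.cos(np.linspace(0, 2 * np.pi, 19))
        else:  # W: two local minima with a small bump between
            # mid-cycle bump stays below the 0.6 mm/s step floor
            v[11:30] = [
                1.0, 0.7, 0.4, 0.2, 0.3, 0.38, 0.45, 0.5, 0.52, 0.53,
                0.52, 0.5, 0.45, 0.38, 0.3, 0.2, 0.4, 0.7, 1.0,
            ]
        s = _bare_series(40, tail_forward_velocity_mm_s=v)
        s.midpoint_mm = np.stack(
            [np.cumsum(v) / 10, np.zeros(40)], axis=1
        )
        s.midpoint_speed_mm_s = v.copy()
        return s

    def test_single_trough_normal(self):
        s = self._cycle_series("clean")
        steps, cycles = detect_steps(s)
        (cyc,) = cycles
        classify_stepping(cycles, s)
        assert cyc.cycle_class == "normal"

    def test_w_shape_stumble(self):
        s = self._cycle_series("W")
        steps, cycles = detect_steps(s)
        (cyc,) = cycles
        classify_stepping(cycles, s)
        assert cyc.cycle_class == "stumble"
        assert cyc.n_minima == 2

    def test_alternating_stumbler_ratio_half(self):
        # 20 cycles, every second one W-shaped -> stumble ratio 0.5
        fps = 10.0
        blocks = []
        for k in range(21):
            blocks.append([1.5])
            if k == 20:
                break
            if k % 2 == 0:
                blocks.append(list(0.6 + 0.3 * np.cos(np.linspace(0, 2 * np.pi, 9))[1:-1]))
            else:
                blocks.append([0.9, 0.4, 0.5, 0.55, 0.5, 0.4, 0.9])
        v = np.concatenate([[0.1]] + blocks + [[0.1]])
        s = _bare_series(len(v), fps=fps, tail_forward_velocity_mm_s=v)
        s.midpoint_mm = np.stack([np.cumsum(v) / fps, np.zeros(len(v))], axis=1)
        s.midpoint_speed_mm_s = v.copy()
        steps, cycles = detect_steps(s)
        classify_stepping(cycles, s)
        ratio = np.mean([c.cycle_class == "stumble" for c in cycles])
        assert ratio == pytest.approx(0.5, abs=0.02)


class TestDetectSwitches:
    def test_step_change_detected(self):
        fps = 10.0
        n = 600
        v = np.full(n, 1.0)
        v[300:] = -1.0  # switch at t = 30 s
        s = _bare_series(n, fps=fps, tail_forward_velocity_bl_s=v)
        events = detect_switches(s)
        assert len(events) == 1
        assert events[0].direction == "to_backward"
        assert events[0].time_s == pytest.approx(30.0, abs=0.6)

    def test_short_blip_ignored(self):
        v = np.full(200, 1.0)
        v[100:102] = -1.0  # 0.2 s blip, persistence 1 s
        s = _bare_series(200, tail_forward_velocity_bl_s=v)
        assert detect_switches(s) == []

    def test_never_negative_empty(self):
        s = _bare_series(100, tail_forward_velocity_bl_s=np.full(100, 0.5))
        assert detect_switches(s) == []

    def test_alternating_directions(self):
        v = np.concatenate([np.full(100, 1.0), np.full(100, -1.0), np.full(100, 1.0)])
        s = _bare_series(300, tail_forward_velocity_bl_s=v)
        events = detect_switches(s)
        assert [e.direction for e in events] == ["to_backward", "to_forward"]


class TestRecoveryFromSimulation:
    def test_step_count_and_interval(self, hc_backward_truth):
        lv = hc_backward_truth
        ev = analyse_track(truth_to_track(lv))
        assert abs(len(ev.steps) - len(lv.step_times_s)) <= 1
        intervals = [c.interval_s for c in ev.cycles]
        assert np.mean(intervals) == pytest.approx(1.0, rel=0.05)

    def test_hc_count_and_sides(self, hc_backward_truth):
        lv = hc_backward_truth
        ev = analyse_track(truth_to_track(lv))
        truth = [h for h in lv.hc_intervals if h.detectable]
        assert len(ev.hcs) == len(truth)
        for det, tru in zip(ev.hcs, truth):
            assert det.side == tru.side
            assert det.start_frame / 16 == pytest.approx(tru.start_s, abs=0.4)

    def test_subthreshold_hcs_missed_entirely(self):
        p = LarvaKinematicParams(hc_rate_hz=0.1, rng_seed=3, hc_amplitude_deg=10.0)
        lv = simulate_track(p, 60, 16).single
        assert len(lv.hc_intervals) > 0
        ev = analyse_track(truth_to_track(lv))
        assert ev.hcs == []

    def test_no_step_inside_exclusion_zone(self, hc_backward_truth):
        ev = analyse_track(truth_to_track(hc_backward_truth))
        for st in ev.steps:
            assert ev.run_mask[st.frame]
            for hc in ev.hcs:
                assert not (
                    hc.start_frame - 1.5 * 16 <= st.frame <= hc.end_frame + 1.5 * 16
                )

    def test_switch_recovery(self, hc_backward_truth):
        ev = analyse_track(truth_to_track(hc_backward_truth))
        times = [(round(s.time_s), s.direction) for s in ev.switches]
        assert times == [(40, "to_backward"), (50, "to_forward")]

    def test_mirror_symmetry(self, hc_backward_truth):
        lv = hc_backward_truth
        track = truth_to_track(lv)
        mirrored = truth_to_track(lv)
        mirrored.spine_mm = mirrored.spine_mm.copy()
        mirrored.spine_mm[..., 1] *= -1
        ev = analyse_track(track)
        ev_m = analyse_track(mirrored)
        assert len(ev.hcs) == len(ev_m.hcs)
        for a, b in zip(ev.hcs, ev_m.hcs):
            assert {a.side, b.side} == {"left", "right"} or a.hc_angle_deg == 0
            assert a.hc_angle_deg == pytest.approx(-b.hc_angle_deg, abs=1e-6)
        assert np.allclose(
            ev.series.bending_angle_deg, -ev_m.series.bending_angle_deg, atol=1e-9
        )
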