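import numpy as np
import pytest
from hypothesis import given, strategies as st

import turnkit as tk
from turnkit.turn_detection import Segment, merge_gradual_turns, subturn_events

from conftest import FS, make_trace


def _halfsine(dur_s, peak_dps, fs=FS):
    t = np.arange(int(dur_s * fs)) / fs
    return peak_dps * np.sin(np.pi * t / dur_s)


def _concat(*parts):
    return np.concatenate(parts)


def _gap(dur_s, fs=FS):
    return np.zeros(int(dur_s * fs))


class TestZeroCrossing:
    def test_single_half_sine_is_one_segment(self):
        w = _concat(_gap(1), _halfsine(2, 100), _gap(1))
        segs = tk.zero_crossing_segments(make_trace(w), deadband_dps=5)
        assert len(segs) == 1
        assert segs[0].angle_deg > 0

    def test_opposite_half_sines_give_two_segments(self):
        w = _concat(_gap(1), _halfsine(2, 100), -_halfsine(2, 100), _gap(1))
        segs = tk.zero_crossing_segments(make_trace(w), deadband_dps=5)
        assert len(segs) == 2
        assert segs[0].sign == 1 and segs[1].sign == -1

    def test_signal_within_deadband_yields_nothing(self):
        w = 3.0 * np.sin(np.linspace(0, 20, 2000))
        assert tk.zero_crossing_segments(make_trace(w), deadband_dps=5) == []

    def test_segment_angle_matches_integral(self):
        w = _concat(_gap(1), _halfsine(2, 100), _gap(1))
        [seg] = tk.zero_crossing_segments(make_trace(w), deadband_dps=0)
        # integral of peak*sin(pi t/T) over T = 2*peak*T/pi
        assert abs(seg.angle_deg - 2 * 100 * 2 / np.pi) < 1.5


def S(start, end, angle):
    return Segment(start_s=start, end_s=end, angle_deg=angle)


class TestGradualTurnMerging:
    def test_three_subturns_become_one_turn(self):
        segs = [S(0.0, 1.0, 60), S(1.3, 2.3, 70), S(2.6, 3.6, 50)]
        merged = merge_gradual_turns(segs)
        assert len(merged) == 1
        assert merged[0].angle_deg == pytest.approx(180.0)
        assert len(merged[0].subturns) == 3
        assert merged[0].start_s == 0.0 and merged[0].end_s == 3.6

    def test_opposite_directions_not_merged(self):
        merged = merge_gradual_turns([S(0, 1, 60), S(1.3, 2.3, -60)])
        assert len(merged) == 2

    def test_wide_gap_not_merged(self):
        merged = merge_gradual_turns([S(0, 1, 60), S(1.6, 2.6, 60)])
        assert len(merged) == 2

    def test_small_jitter_segment_does_not_break_chain(self):
        segs = [S(0, 1, 60), S(1.1, 1.2, -4), S(1.3, 2.3, 70)]
        merged = merge_gradual_turns(segs)
        assert len(merged) == 1
        assert merged[0].angle_deg == pytest.approx(130.0)

    def test_subturn_angles_sum_to_merged_angle(self):
        segs = [S(0, 1, 55.5), S(1.2, 2, 61.25), S(2.3, 3, 63.25)]
        [m] = merge_gradual_turns(segs)
        assert sum(a for _, _, a in m.subturns) == pytest.approx(m.angle_deg)

    @given(st.lists(
        st.tuples(st.floats(0, 30), st.floats(0.1, 3),
                  st.floats(-90, 90)),
        min_size=0, max_size=8))
    def test_merging_is_idempotent(self, raw):
        segs, cur = [], 0.0
        for gap, dur, angle in raw:
            start = cur + gap
            segs.append(S(start, start + dur, angle))
            cur = start + dur
        once = merge_gradual_turns(segs)
        twice = merge_gradual_turns(once)
        assert [(m.start_s, m.end_s, m.angle_deg) for m in once] == \
               [(m.start_s, m.end_s, m.angle_deg) for m in twice]


class TestTurnAcceptance:
    def _trace_with_turn(self, angle, dur):
        peak = angle * np.pi / (2 * dur)  # half-sine peak for target angle
        w = _concat(_gap(2), _halfsine(dur, peak), _gap(2))
        return make_trace(w)

    @pytest.mark.parametrize("angle,dur,accepted", [
        (85, 2.0, False),    # under the 90 deg L5 threshold
        (178, 3.0, True),
        (120, 14.0, False),  # too long even after deadband trimming
        (95, 0.3, False),    # too short
        (-178, 3.0, True),   # left turns count too
    ])
    def test_l5_threshold_and_duration_rules(self, angle, dur, accepted):
        turns = tk.detect_turns(self._trace_with_turn(angle, dur), "L5")
        assert (len(turns) == 1) == accepted

    def test_head_uses_30_degree_threshold(self):
        trace = self._trace_with_turn(40, 2.0)
        assert len(tk.detect_turns(trace, "HD")) == 1
        assert len(tk.detect_turns(trace, "L5")) == 0

    def test_unknown_location_is_fatal(self):
        with pytest.raises(ValueError, match="location"):
            tk.detect_turns(self._trace_with_turn(100, 2.0), "XX")

    def test_direction_follows_sign(self):
        [left] = tk.detect_turns(self._trace_with_turn(-178, 3.0), "L5")
        assert left.direction == tk.Direction.LEFT
        assert left.angle_deg < 0


class TestInnerOuter:
    def test_right_turn_mapping(self):
        turn = tk.TurnEvent("L5", 0, 2, 170.0)
        assert tk.assign_inner_outer(turn) == {"inner": "RA", "outer": "LA"}

    def test_left_turn_mapping(self):
        turn = tk.TurnEvent("L5", 0, 2, -170.0)
        assert tk.assign_inner_outer(turn) == {"inner": "LA", "outer": "RA"}

    def test_roles_swap_between_opposite_turns(self):
        t1 = tk.TurnEvent("L5", 0, 2, 170.0)
        t2 = tk.TurnEvent("L5", 10, 12, -170.0)
        m1, m2 = tk.assign_inner_outer(t1), tk.assign_inner_outer(t2)
        assert m1["inner"] == m2["outer"] == "RA"


class TestStepCounting:
    def _steps_trace(self, n_steps, step_angle=60.0, step_dur=0.4, gap=0.45):
        parts = [_gap(1)]
        peak = step_angle * np.pi / (2 * step_dur)
        for _ in range(n_steps):
            parts += [_halfsine(step_dur, peak), _gap(gap)]
        parts.append(_gap(1))
        return make_trace(_concat(*parts), location="RA")

    def test_three_discrete_rotations_are_three_steps(self):
        trace = self._steps_trace(3)
        steps = tk.count_steps(trace, (1.0, 4.0), tk.Direction.RIGHT, "inner")
        assert len(steps) == 3
        for s in steps:
            assert s.angle_deg >= 30

    def test_motionless_ankle_has_no_steps(self):
        trace = make_trace(np.zeros(1000), location="RA")
        assert tk.count_steps(trace, (1.0, 4.0), tk.Direction.RIGHT, "inner") == []

    def test_continuous_pivot_is_one_step(self):
        w = _concat(_gap(1), _halfsine(2.0, 180 * np.pi / 4), _gap(1))
        trace = make_trace(w, location="RA")
        steps = tk.count_steps(trace, (1.0, 3.0), tk.Direction.RIGHT, "inner")
        assert len(steps) == 1

    def test_wrong_direction_rotations_ignored(self):
        trace = self._steps_trace(3)
        steps = tk.count_steps(trace, (1.0, 4.0), tk.Direction.LEFT, "inner")
        assert steps == []


class TestSubturnBookkeeping:
    def test_subturn_events_expand_merged_turn(self):
        segs = [S(0, 1, 60), S(1.3, 2.3, 70)]
        [m] = merge_gradual_turns(segs)
        turn = tk.TurnEvent("L5", m.start_s, m.end_s, m.angle_deg,
                            subturns=m.subturns)
        subs = subturn_events(turn)
        assert len(subs) == 2
        assert sum(s.angle_deg for s in subs) == pytest.approx(turn.angle_deg)


class TestEndToEndDetection:
    def test_noiseless_counts_match_ground_truth(self, noiseless_analysis,
                                                 noiseless_session):
        _, truth = noiseless_session
        assert len(noiseless_analysis.l5_turns) == len(truth.l5_turns)
        for det, true in zip(noiseless_analysis.l5_turns, truth.l5_turns):
            assert det.direction == true.direction

    def test_noiseless_step_counts_match(self, noiseless_analysis,
                                         noiseless_session):
        _, truth = noiseless_session
        for det_pt, true_pt in zip(noiseless_analysis.steps_by_turn,
                                   truth.steps_by_turn):
            for role in ("inner", "outer"):
                assert len(det_pt[role]) == len(true_pt[role])
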