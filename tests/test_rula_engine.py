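import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rulatime import rula_engine as eng
from rulatime.rula_engine import (
    RulaInputError,
    StaticWindowConfig,
    muscle_use_score,
    score_frame,
    score_lower_arm,
    score_neck,
    score_recording,
    score_trunk,
    score_upper_arm,
    score_wrist,
    table_a,
    table_b,
    table_c,
)

import oracle_rula as oracle
from conftest import make_frame, make_recording


class TestStepScores:
    @pytest.mark.parametrize(
        "flexion,flags,expected",
        [
            (10.0, {}, 1),
            (100.0, dict(abducted=True, shoulder_raised=True), 6),
            (20.0, {}, 1),  # boundary goes to the milder band
            (-30.0, {}, 2),
            (70.0, dict(supported=True), 2),
        ],
    )
    def test_upper_arm_bands_and_adjustments(self, flexion, flags, expected):
        assert score_upper_arm(flexion, **flags) == expected

    @pytest.mark.parametrize(
        "flexion,across,expected",
        [(80.0, False, 1), (30.0, True, 3), (100.0, False, 1), (110.0, False, 2)],
    )
    def test_lower_arm(self, flexion, across, expected):
        assert score_lower_arm(flexion, across) == expected

    @pytest.mark.parametrize(
        "args,expected",
        [
            ((0.0, 0.0, False), (1, 1, 2)),
            ((20.0, 12.0, True), (4, 2, 6)),
            ((-10.0, 0.0, False), (2, 1, 3)),
            ((15.0, 0.0, False), (2, 1, 3)),  # boundary milder band
        ],
    )
    def test_wrist_combination(self, args, expected):
        assert score_wrist(*args) == expected

    @pytest.mark.parametrize(
        "args,expected",
        [
            ((5.0, 0.0, 0.0), 1),
            ((25.0, 20.0, 15.0), 5),
            ((-5.0, 0.0, 0.0), 4),  # extension band
            ((20.0, 0.0, 0.0), 2),
        ],
    )
    def test_neck(self, args, expected):
        assert score_neck(*args) == expected

    @pytest.mark.parametrize(
        "args,expected",
        [
            ((0.0, 0.0, 0.0, True), 1),  # sitting, well supported
            ((30.0, 15.0, 15.0, False), 5),
            ((70.0, 0.0, 0.0, False), 4),
            ((-10.0, 0.0, 0.0, False), 2),  # extension beyond neutral band
        ],
    )
    def test_trunk(self, args, expected):
        assert score_trunk(*args) == expected

    def test_non_finite_angle_rejected(self):
        with pytest.raises(RulaInputError):
            score_upper_arm(float("nan"))
        with pytest.raises(RulaInputError):
            score_neck(float("inf"))
        with pytest.raises(RulaInputError):
            score_wrist(0.0, -1.0)


class TestTables:
    def test_worksheet_corners(self):
        assert table_a(1, 1, 1, 1) == 1
        assert table_a(6, 3, 4, 2) == 9
        assert table_b(1, 1, 1) == 1
        assert table_b(6, 6, 2) == 9
        assert table_c(1, 1) == 1
        assert table_c(8, 7) == 7
        assert table_c(12, 9) == 7  # saturation

    def test_exhaustive_equality_with_independent_transcription(self):
        for ua, la, wp, wt in itertools.product(
            range(1, 7), range(1, 4), range(1, 5), range(1, 3)
        ):
            assert table_a(ua, la, wp, wt) == oracle.oracle_table_a(ua, la, wp, wt)
        for n, t, lg in itertools.product(range(1, 7), range(1, 7), range(1, 3)):
            assert table_b(n, t, lg) == oracle.oracle_table_b(n, t, lg)
        for sc, sd in itertools.product(range(1, 13), range(1, 10)):
            assert table_c(sc, sd) == oracle.oracle_table_c(sc, sd)

    def test_exhaustive_monotonicity(self):
        """Worsening any single input never lowers the looked-up score."""
        for ua, la, wp, wt in itertools.product(
            range(1, 7), range(1, 4), range(1, 5), range(1, 3)
        ):
            v = table_a(ua, la, wp, wt)
            if ua < 6:
                assert table_a(ua + 1, la, wp, wt) >= v
            if la < 3:
                assert table_a(ua, la + 1, wp, wt) >= v
            if wp < 4:
                assert table_a(ua, la, wp + 1, wt) >= v
            if wt < 2:
                assert table_a(ua, la, wp, wt + 1) >= v
        for n, t, lg in itertools.product(range(1, 7), range(1, 7), range(1, 3)):
            v = table_b(n, t, lg)
            if n < 6:
                assert table_b(n + 1, t, lg) >= v
            if t < 6:
                assert table_b(n, t + 1, lg) >= v
            if lg < 2:
                assert table_b(n, t, lg + 1) >= v
        for sc, sd in itertools.product(range(1, 9), range(1, 8)):
            v = table_c(sc, sd)
            if sc < 8:
                assert table_c(sc + 1, sd) >= v
            if sd < 7:
                assert table_c(sc, sd + 1) >= v

    def test_out_of_range_rejected(self):
        with pytest.raises(RulaInputError):
            table_a(0, 1, 1, 1)
        with pytest.raises(RulaInputError):
            table_b(1, 7, 1)
        with pytest.raises(RulaInputError):
            table_c(0, 1)


class TestMuscleUse:
    def test_constant_posture_fires_after_window(self):
        rate, cfg = 24.0, StaticWindowConfig()
        n = int(90 * rate)
        angles = np.zeros((n, 2))
        scores = np.ones(n, dtype=int)
        m = muscle_use_score(angles, scores, rate, cfg)
        win = int(60 * rate)
        assert np.all(m[win - 1:] == 1)
        assert np.all(m[: win - 1] == 0)

    def test_repetition_rule_fires_on_band_alternation(self):
        rate = 24.0
        n = int(120 * rate)
        # alternate score bands 6x per minute => crossings every 10 s
        t = np.arange(n) / rate
        scores = (np.floor(t / 10) % 2 + 1).astype(int)
        angles = (scores * 30.0)[:, None]  # moves with the band: not static
        m = muscle_use_score(angles, scores, rate)
        assert np.all(m[int(60 * rate):] == 1)

    def test_slow_drift_with_single_change_scores_zero(self):
        rate = 24.0
        n = int(120 * rate)
        t = np.arange(n) / rate
        angles = (t * 6.0 / 60.0)[:, None]  # 6 deg per minute drift
        scores = np.where(t < 60, 1, 2)
        m = muscle_use_score(angles, scores, rate)
        assert np.all(m[int(60 * rate):] == 0)


class TestScoreFrame:
    def test_neutral_seated_frame_walkthrough(self, neutral_frame):
        s = score_frame(neutral_frame, side="r", muscle_a=1, muscle_b=1)
        assert s.table_a == 1 and s.table_b == 1
        assert s.score_c == 2 and s.score_d == 2
        assert s.final == table_c(2, 2)

    def test_extreme_frame_saturates_to_seven(self):
        frame = make_frame(
            upper_arm_flexion_r=120.0,
            shoulder_raise_flag_r=True,
            upper_arm_abduction_r=60.0,
            lower_arm_flexion_r=10.0,
            arm_across_midline_flag_r=True,
            wrist_flexion_r=40.0,
            wrist_deviation_r=20.0,
            wrist_twist_endrange_flag_r=True,
            neck_flexion=-10.0,
            neck_rotation=30.0,
            neck_side_bend=30.0,
            trunk_flexion=70.0,
            trunk_rotation=30.0,
            trunk_side_bend=30.0,
            trunk_supported_flag=False,
            legs_supported_flag=False,
        )
        s = score_frame(frame, side="r", muscle_a=1, muscle_b=1)
        assert (s.upper_arm, s.lower_arm, s.wrist_posture, s.wrist_twist) == (6, 3, 4, 2)
        assert (s.neck, s.trunk, s.legs) == (6, 6, 2)
        assert s.final == 7

    def test_supplied_abduction_flag_wins_over_angle(self):
        frame = make_frame(upper_arm_flexion_r=10.0)
        frame["arm_abducted_flag_r"] = True  # supplied flag, angle is 0
        assert score_frame(frame, side="r").upper_arm == 2

    def test_derived_abduction_flag_strict_threshold(self):
        assert score_frame(make_frame(upper_arm_abduction_r=45.0), "r").upper_arm == 1
        assert score_frame(make_frame(upper_arm_abduction_r=50.0), "r").upper_arm == 2

    @settings(max_examples=400, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_independent_worksheet_transcription(self, data):
        """Engine equals the straight-line worksheet walk on random frames."""
        grid = st.sampled_from([round(-180 + 5 * i, 1) for i in range(73)])
        dev = st.sampled_from([0.0, 5.0, 10.0, 12.0, 20.0])
        flag = st.booleans()
        frame = make_frame()
        for side in ("r", "l"):
            frame[f"upper_arm_flexion_{side}"] = data.draw(grid)
            frame[f"upper_arm_abduction_{side}"] = abs(data.draw(grid))
            frame[f"lower_arm_flexion_{side}"] = data.draw(grid)
            frame[f"wrist_flexion_{side}"] = data.draw(grid)
            frame[f"wrist_deviation_{side}"] = data.draw(dev)
            for f in ("shoulder_raise_flag", "arm_supported_flag",
                      "arm_across_midline_flag", "wrist_twist_endrange_flag"):
                frame[f"{f}_{side}"] = data.draw(flag)
        for c in ("neck_flexion", "neck_rotation", "neck_side_bend",
                  "trunk_flexion", "trunk_rotation", "trunk_side_bend"):
            frame[c] = data.draw(grid)
        frame["trunk_supported_flag"] = data.draw(flag)
        frame["legs_supported_flag"] = data.draw(flag)
        side = data.draw(st.sampled_from(["r", "l"]))
        muscle_a, muscle_b = data.draw(flag), data.draw(flag)
        got = score_frame(frame, side, int(muscle_a), int(muscle_b))
        want = oracle.oracle_score_frame(frame, side, int(muscle_a), int(muscle_b))
        for key, val in want.items():
            assert getattr(got, key) == val, key

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_single_angle_worsening_never_lowers_final(self, data):
        """Pushing one posture angle deeper into a worse band is monotone."""
        grid = st.sampled_from([round(-90 + 5 * i, 1) for i in range(37)])
        frame = make_frame(
            upper_arm_flexion_r=abs(data.draw(grid)),
            wrist_flexion_r=data.draw(grid),
            neck_flexion=abs(data.draw(grid)),
            trunk_flexion=abs(data.draw(grid)),
        )
        channel = data.draw(
            st.sampled_from(
                ["upper_arm_flexion_r", "wrist_flexion_r", "neck_flexion", "trunk_flexion"]
            )
        )
        base = score_frame(frame, "r")
        worse = dict(frame)
        # move deeper into flexion (all four channels worsen with magnitude)
        worse[channel] = abs(worse[channel]) + data.draw(st.sampled_from([5.0, 25.0, 60.0]))
        after = score_frame(worse, "r")
        assert after.final >= base.final

    def test_bad_muscle_force_rejected(self, neutral_frame):
        with pytest.raises(RulaInputError):
            score_frame(neutral_frame, "r", muscle_a=2)
        with pytest.raises(RulaInputError):
            score_frame(neutral_frame, "r", force_a=4)


class TestScoreRecording:
    def test_static_high_risk_minute_is_mostly_seven(self):
        frame = make_frame(
            upper_arm_flexion_r=32.0,
            lower_arm_flexion_r=45.0,
            arm_across_midline_flag_r=True,
            wrist_flexion_r=25.0,
            wrist_deviation_r=20.0,
            neck_flexion=30.0,
            neck_rotation=20.0,
            trunk_flexion=32.0,
        )
        rec = make_recording(n_frames=24 * 60, frame=frame)
        scores = score_recording(rec)
        assert (scores["final"] == 7).mean() >= 0.95

    def test_deterministic(self):
        rec = make_recording(n_frames=100)
        assert score_recording(rec).equals(score_recording(rec))

    def test_left_perturbation_leaves_right_arm_scores_unchanged(self):
        rec_a = make_recording(n_frames=50)
        frame = make_frame(upper_arm_flexion_l=80.0, wrist_flexion_l=30.0)
        rec_b = make_recording(n_frames=50, frame=frame)
        a, b = score_recording(rec_a), score_recording(rec_b)
        for col in ("upper_arm_r", "lower_arm_r", "wrist_combined_r", "table_a_r"):
            np.testing.assert_array_equal(a[col], b[col])
        assert (b["upper_arm_l"] > a["upper_arm_l"]).all()

    def test_empty_recording_rejected(self):
        rec = make_recording(n_frames=1)
        rec.data = rec.data.iloc[:0]
        with pytest.raises(RulaInputError):
            score_recording(rec)

    def test_step_maxima_respected_on_random_postures(self, rng):
        n = 2000
        cols = {}
        for c in ("upper_arm_flexion_r", "upper_arm_flexion_l", "wrist_flexion_r",
                  "wrist_flexion_l", "neck_flexion", "trunk_flexion",
                  "neck_rotation", "trunk_rotation", "neck_side_bend",
                  "trunk_side_bend", "lower_arm_flexion_r", "lower_arm_flexion_l"):
            cols[c] = rng.uniform(-170, 170, n)
        for c in ("wrist_deviation_r", "wrist_deviation_l"):
            cols[c] = rng.uniform(0, 40, n)
        for c in ("shoulder_raise_flag_r", "arm_across_midline_flag_r",
                  "wrist_twist_endrange_flag_r", "legs_supported_flag"):
            cols[c] = rng.random(n) < 0.5
        rec = make_recording(n_frames=n, columns=cols)
        s = score_recording(rec)
        for col, hi in [("upper_arm_r", 6), ("upper_arm_l", 6), ("lower_arm_r", 3),
                        ("lower_arm_l", 3), ("wrist_combined_r", 6),
                        ("wrist_combined_l", 6), ("neck", 6), ("trunk", 6),
                        ("final", 7), ("final_r", 7), ("final_l", 7)]:
            assert s[col].between(1, hi).all(), col
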