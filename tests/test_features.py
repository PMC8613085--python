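"""Kinematic features: hand-derived examples, a brute-force oracle on
short trajectories, and invariance properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mousestress as ms
from mousestress.features import (
    TrialSegment,
    acceleration_stats,
    angle_stats,
    directional_changes,
    ideal_line_deviation,
    in_circle_ratio,
    speed_stats,
    time_features,
    total_distance,
)
from mousestress.preprocess import UniformTrajectory


def _traj(points, dt=15.0):
    return UniformTrajectory(dt=dt, origin_t=0, points=np.asarray(points, float))


class TestSpeed:
    def test_constant_speed_diagonal(self):
        m, sd = speed_stats(_traj([(0, 0), (3, 4), (6, 8)]))
        assert m == pytest.approx(5 / 0.015)
        assert sd == pytest.approx(0.0)

    def test_one_pixel_step(self):
        m, _ = speed_stats(_traj([(0, 0), (0, 1)]))
        assert m == pytest.approx(1 / 0.015)

    def test_spatial_homogeneity(self):
        pts = [(0, 0), (2, 5), (9, 1), (4, 4)]
        m1, s1 = speed_stats(_traj(pts))
        m2, s2 = speed_stats(_traj([(2 * x, 2 * y) for x, y in pts]))
        assert m2 == pytest.approx(2 * m1)
        assert s2 == pytest.approx(2 * s1)


class TestAcceleration:
    def test_constant_speed_all_zero(self):
        assert acceleration_stats(_traj([(0, 0), (1, 0), (2, 0)])) == (0, 0, 0, 0)

    def test_speed_up_then_down(self):
        # speeds 100, 200, 100 px/s at dt = 15 ms
        d = 100 * 0.015
        pts = [(0, 0), (d, 0), (d + 2 * d, 0), (d + 2 * d + d, 0)]
        pm, ps, nm, ns = acceleration_stats(_traj(pts))
        assert pm == pytest.approx(100 / 0.015)
        assert nm == pytest.approx(-100 / 0.015)
        assert ps == pytest.approx(0.0, abs=1e-9)
        assert ns == pytest.approx(0.0, abs=1e-9)

    def test_uniform_acceleration_has_zero_sd(self):
        pm, ps, nm, ns = acceleration_stats(_traj([(0, 0), (1, 0), (3, 0), (6, 0)]))
        assert pm == pytest.approx((200 - 200 / 3) / 2 / 0.015, rel=1e-9)
        assert ps == pytest.approx(0.0, abs=1e-6)
        assert (nm, ns) == (0.0, 0.0)


class TestAngles:
    @pytest.mark.parametrize(
        "pts,expected",
        [
            ([(0, 0), (1, 0), (2, 0)], 0.0),
            ([(0, 0), (1, 0), (1, 1)], 90.0),
            ([(0, 0), (1, 0), (0, 0)], 180.0),
        ],
    )
    def test_hand_examples(self, pts, expected):
        m, sd = angle_stats(_traj(pts))
        assert m == pytest.approx(expected)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_zero_length_segments_skipped(self):
        # the duplicate point invalidates its two adjacent angle pairs;
        # only the first (collinear) pair survives
        m, sd = angle_stats(_traj([(0, 0), (1, 0), (2, 0), (2, 0), (3, 0)]))
        assert m == pytest.approx(0.0)
        assert sd == pytest.approx(0.0)

    def test_all_degenerate_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            angle_stats(_traj([(1, 1), (1, 1), (1, 1)]))


class TestFlips:
    @pytest.mark.parametrize(
        "xs,expected",
        [
            ([0, 1, 2, 1, 2], 2),
            ([0, 1, 2, 3], 0),
            ([0, 1, 1, 0], 1),  # zero delta ignored
        ],
    )
    def test_x_direction(self, xs, expected):
        pts = [(x, 0) for x in xs]
        xf, yf = directional_changes(_traj(pts))
        assert xf == expected
        assert yf == 0


class TestDistance:
    def test_l_shape(self):
        assert total_distance(_traj([(0, 0), (3, 0), (3, 4)])) == pytest.approx(7)

    def test_single_point(self):
        assert total_distance(_traj([(5, 5)])) == 0.0

    def test_retraced_ground_counts(self):
        assert total_distance(_traj([(0, 0), (5, 0), (0, 0)])) == pytest.approx(10)


class TestTimeFeatures:
    def _session(self, events, task=ms.Task.SLIDER):
        geom = ms.TaskGeometry(
            task=task,
            trials=[{"track_y": 1.0, "start_x": 1.0, "target_x": 2.0, "half_w": 1.0}]
            * 12,
        )
        return ms.TaskSession(
            participant_id="p",
            task=task,
            stage=ms.Stage.BASELINE,
            condition=ms.Condition.LOW_STRESS,
            screen_w=1280,
            screen_h=800,
            events=events,
            geometry=geom,
        )

    def test_click_marks_work_start(self):
        events = [
            ms.MouseEvent("move", 0, 0, 1000),
            ms.MouseEvent("click_down", 1, 1, 1600),
            ms.MouseEvent("move", 2, 2, 5000),
        ]
        task_t, work_t = time_features(self._session(events))
        assert task_t == pytest.approx(4.0)
        assert work_t == pytest.approx(3.4)

    def test_work_start_at_first_event_makes_both_equal(self):
        events = [
            ms.MouseEvent("click_down", 0, 0, 500),
            ms.MouseEvent("move", 2, 2, 2500),
        ]
        task_t, work_t = time_features(self._session(events))
        assert task_t == work_t

    def test_never_entering_circle_raises(self):
        geom = ms.TaskGeometry(
            task=ms.Task.FOLLOW_CIRCLE,
            trials=[{"cx": 500.0, "cy": 400.0, "path_r": 150.0, "circle_r": 30.0,
                     "omega": 0.25, "theta0": 0.0, "duration_s": 25.0}],
        )
        s = ms.TaskSession(
            participant_id="p", task=ms.Task.FOLLOW_CIRCLE, stage=ms.Stage.BASELINE,
            condition=ms.Condition.LOW_STRESS, screen_w=1280, screen_h=800,
            events=[ms.MouseEvent("move", 0, 0, 0), ms.MouseEvent("move", 5, 5, 100)],
            geometry=geom,
        )
        with pytest.raises(ValueError, match="circle"):
            time_features(s)


class TestDeviation:
    def test_on_line_samples_zero(self):
        tr = _traj([(0, 0), (5, 0), (10, 0)])
        seg = TrialSegment(start=(0, 0), end=(10, 0), indices=[0, 1, 2])
        assert ideal_line_deviation(tr, [seg]) == (0, 0, 0)

    def test_symmetric_offsets(self):
        tr = _traj([(5, 3), (5, -3)])
        seg = TrialSegment(start=(0, 0), end=(10, 0), indices=[0, 1])
        total, mean, sd = ideal_line_deviation(tr, [seg])
        assert (total, mean, sd) == (pytest.approx(6), pytest.approx(3), pytest.approx(0))

    def test_single_sample(self):
        tr = _traj([(0, 4)])
        seg = TrialSegment(start=(0, 0), end=(10, 0), indices=[0])
        assert ideal_line_deviation(tr, [seg]) == (pytest.approx(4),) * 2 + (0,)

    def test_degenerate_trial_uses_distance_to_point(self):
        tr = _traj([(3, 4)])
        seg = TrialSegment(start=(0, 0), end=(0, 0), indices=[0])
        total, _, _ = ideal_line_deviation(tr, [seg])
        assert total == pytest.approx(5)

    def test_overshoot_past_endpoint_registers(self):
        # infinite line, not the segment: a point beyond the end but on the
        # line has zero deviation; one beside it keeps its perpendicular
        tr = _traj([(15, 0), (15, 2)])
        seg = TrialSegment(start=(0, 0), end=(10, 0), indices=[0, 1])
        total, _, _ = ideal_line_deviation(tr, [seg])
        assert total == pytest.approx(2)


class TestInCircleRatio:
    def _geom(self):
        return ms.TaskGeometry(
            task=ms.Task.FOLLOW_CIRCLE,
            trials=[{"cx": 0.0, "cy": 0.0, "path_r": 0.0, "circle_r": 10.0,
                     "omega": 0.0, "theta0": 0.0, "duration_s": 25.0}],
        )

    def test_half_inside(self):
        pts = [(0, 0)] * 50 + [(100, 100)] * 50
        assert in_circle_ratio(_traj(pts), self._geom(), 0) == pytest.approx(1.0)

    def test_never_inside(self):
        pts = [(100, 100)] * 20
        assert in_circle_ratio(_traj(pts), self._geom(), 0) == 0.0

    def test_always_inside_floored_denominator(self):
        pts = [(0, 0)] * 100
        assert in_circle_ratio(_traj(pts), self._geom(), 0) == pytest.approx(100.0)


class TestExtractFeatures:
    @pytest.mark.parametrize(
        "task,n_expected",
        [
            (ms.Task.POINT_AND_CLICK, 16),
            (ms.Task.DRAG_AND_DROP, 16),
            (ms.Task.SLIDER, 13),
            (ms.Task.FOLLOW_CIRCLE, 14),
        ],
    )
    def test_per_task_feature_counts(self, small_cohort, task, n_expected):
        s = small_cohort.sessions[("p0000", task, ms.Stage.BASELINE)]
        assert len(ms.extract_features(s)) == n_expected

    def test_deterministic_on_identical_sessions(self, small_cohort):
        s = small_cohort.sessions[("p0002", ms.Task.SLIDER, ms.Stage.APPLICATION)]
        assert ms.extract_features(s).values == ms.extract_features(s).values

    def test_masked_features_absent_not_zero(self, small_cohort):
        s = small_cohort.sessions[("p0000", ms.Task.SLIDER, ms.Stage.BASELINE)]
        fv = ms.extract_features(s)
        assert "dev_total" not in fv
        assert "in_circle_ratio" not in fv


# ---------------------------------------------------------------------------
# Brute-force oracle: independent re-computation from the definitions


def _oracle(points, dt_s=0.015):
    pts = [tuple(map(float, p)) for p in points]
    speeds = [
        math.dist(pts[i], pts[i + 1]) / dt_s for i in range(len(pts) - 1)
    ]
    accs = [(speeds[i + 1] - speeds[i]) / dt_s for i in range(len(speeds) - 1)]
    pos = [a for a in accs if a > 0]
    neg = [a for a in accs if a < 0]

    def mean(v):
        return sum(v) / len(v)

    def psd(v):
        m = mean(v)
        return math.sqrt(sum((x - m) ** 2 for x in v) / len(v))

    angles = []
    for i in range(len(pts) - 2):
        ux, uy = pts[i + 1][0] - pts[i][0], pts[i + 1][1] - pts[i][1]
        wx, wy = pts[i + 2][0] - pts[i + 1][0], pts[i + 2][1] - pts[i + 1][1]
        nu, nw = math.hypot(ux, uy), math.hypot(wx, wy)
        if nu == 0 or nw == 0:
            continue
        c = max(-1.0, min(1.0, (ux * wx + uy * wy) / (nu * nw)))
        angles.append(math.degrees(math.acos(c)))

    def flips(axis):
        deltas = [
            pts[i + 1][axis] - pts[i][axis]
            for i in range(len(pts) - 1)
            if pts[i + 1][axis] != pts[i][axis]
        ]
        return sum(
            1
            for i in range(len(deltas) - 1)
            if (deltas[i] > 0) != (deltas[i + 1] > 0)
        )

    return {
        "speed_mean": mean(speeds),
        "speed_sd": psd(speeds),
        "acc_pos_mean": mean(pos) if pos else 0.0,
        "acc_pos_sd": psd(pos) if pos else 0.0,
        "acc_neg_mean": mean(neg) if neg else 0.0,
        "acc_neg_sd": psd(neg) if neg else 0.0,
        "dist_total": sum(
            math.dist(pts[i], pts[i + 1]) for i in range(len(pts) - 1)
        ),
        "angle_mean": mean(angles) if angles else None,
        "angle_sd": psd(angles) if angles else None,
        "xflips": flips(0),
        "yflips": flips(1),
    }


@given(
    st.lists(
        st.tuples(st.integers(0, 40), st.integers(0, 40)),
        min_size=3,
        max_size=10,
    )
)
@settings(max_examples=200, deadline=None)
def test_features_match_brute_force_oracle(points):
    tr = _traj(points)
    expect = _oracle(points)
    sm, ssd = speed_stats(tr)
    assert sm == pytest.approx(expect["speed_mean"], rel=1e-12)
    assert ssd == pytest.approx(expect["speed_sd"], rel=1e-9, abs=1e-9)
    pm, ps, nm, ns = acceleration_stats(tr)
    assert pm == pytest.approx(expect["acc_pos_mean"], rel=1e-9, abs=1e-9)
    assert ps == pytest.approx(expect["acc_pos_sd"], rel=1e-9, abs=1e-6)
    assert nm == pytest.approx(expect["acc_neg_mean"], rel=1e-9, abs=1e-9)
    assert ns == pytest.approx(expect["acc_neg_sd"], rel=1e-9, abs=1e-6)
    assert total_distance(tr) == pytest.approx(expect["dist_total"], rel=1e-12)
    assert directional_changes(tr) == (expect["xflips"], expect["yflips"])
    if expect["angle_mean"] is not None:
        am, asd = angle_stats(tr)
        assert am == pytest.approx(expect["angle_mean"], rel=1e-9, abs=1e-9)
        assert asd == pytest.approx(expect["angle_sd"], rel=1e-9, abs=1e-6)


@given(
    st.lists(
        st.tuples(st.integers(0, 40), st.integers(0, 40)),
        min_size=3,
        max_size=10,
    ),
    st.integers(-20, 100),
    st.integers(-20, 100),
)
@settings(max_examples=60, deadline=None)
def test_translation_invariance(points, dx, dy):
    tr1 = _traj(points)
    tr2 = _traj([(x + dx, y + dy) for x, y in points])
    assert speed_stats(tr1) == pytest.approx(speed_stats(tr2))
    assert total_distance(tr1) == pytest.approx(total_distance(tr2))
    assert directional_changes(tr1) == directional_changes(tr2)
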