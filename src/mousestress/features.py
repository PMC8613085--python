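"""Kinematic features of a resampled cursor trajectory.

Seventeen features in three blocks — temporal (task/working time, speed,
signed acceleration), spatial (path length, turning angle, directional
changes) and task-specific (deviation from the ideal trial line,
pursuit in-circle ratio).  Applicability depends on the task:
point-and-click and drag-and-drop get 16 features, the slider 13 and
the pursuit task 14; inapplicable features are absent, never zero-filled.

All statistics use the population (n) standard deviation.  Speeds are
px/s over consecutive grid samples; accelerations px/s² over consecutive
speeds; angles are absolute turning magnitudes in [0, 180] degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import EventKind, Task, TaskGeometry, TaskSession
from .preprocess import TooFewPointsError, UniformTrajectory, preprocess_session, remove_artifacts

__all__ = [
    "FeatureVector",
    "TrialSegment",
    "speed_stats",
    "acceleration_stats",
    "angle_stats",
    "directional_changes",
    "total_distance",
    "time_features",
    "ideal_line_deviation",
    "in_circle_ratio",
    "extract_features",
    "segment_trials",
    "COMMON_FEATURES",
    "TASK_FEATURES",
    "ALL_FEATURES",
]

COMMON_FEATURES = (
    "task_time_s",
    "working_time_s",
    "speed_mean",
    "speed_sd",
    "acc_pos_mean",
    "acc_pos_sd",
    "acc_neg_mean",
    "acc_neg_sd",
    "dist_total",
    "angle_mean",
    "angle_sd",
    "xflips",
    "yflips",
)
DEVIATION_FEATURES = ("dev_total", "dev_mean", "dev_sd")

#: Feature applicability per task (16 / 16 / 13 / 14).
TASK_FEATURES = {
    Task.POINT_AND_CLICK: COMMON_FEATURES + DEVIATION_FEATURES,
    Task.DRAG_AND_DROP: COMMON_FEATURES + DEVIATION_FEATURES,
    Task.SLIDER: COMMON_FEATURES,
    Task.FOLLOW_CIRCLE: COMMON_FEATURES + ("in_circle_ratio",),
}
ALL_FEATURES = COMMON_FEATURES + DEVIATION_FEATURES + ("in_circle_ratio",)


@dataclass
class TrialSegment:
    """One trial's ideal-line endpoints and its trajectory samples."""

    start: tuple[float, float]
    end: tuple[float, float]
    indices: np.ndarray  # contiguous sample indices of the trajectory

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)


@dataclass
class FeatureVector:
    """Named feature values for one session, masked to the task."""

    task: Task
    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def __len__(self) -> int:
        return len(self.values)


def _pop_sd(a: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - a.mean()) ** 2)))


def _speeds(tr: UniformTrajectory) -> np.ndarray:
    d = np.linalg.norm(np.diff(tr.points, axis=0), axis=1)
    return d / (tr.dt / 1000.0)


def speed_stats(tr: UniformTrajectory) -> tuple[float, float]:
    """Mean and population SD of sample-to-sample cursor speed, px/s."""
    if len(tr) < 2:
        raise TooFewPointsError("speed needs at least 2 points")
    v = _speeds(tr)
    return float(v.mean()), _pop_sd(v)


def acceleration_stats(tr: UniformTrajectory) -> tuple[float, float, float, float]:
    """Mean/SD of positive and of negative speed change, px/s².

    An empty sign class yields 0 for both its mean and SD so the feature
    table stays rectangular.
    """
    if len(tr) < 3:
        raise TooFewPointsError("acceleration needs at least 3 points")
    v = _speeds(tr)
    a = np.diff(v) / (tr.dt / 1000.0)
    pos = a[a > 0]
    neg = a[a < 0]
    pos_mean, pos_sd = (float(pos.mean()), _pop_sd(pos)) if len(pos) else (0.0, 0.0)
    neg_mean, neg_sd = (float(neg.mean()), _pop_sd(neg)) if len(neg) else (0.0, 0.0)
    return pos_mean, pos_sd, neg_mean, neg_sd


def angle_stats(tr: UniformTrajectory) -> tuple[float, float]:
    """Mean/SD of turning angles between consecutive movement vectors.

    The angle between segments (p_i→p_{i+1}) and (p_{i+1}→p_{i+2}) via
    arccos of the normalized dot product, degrees in [0, 180]; pairs with
    a zero-length segment are skipped.
    """
    if len(tr) < 3:
        raise TooFewPointsError("angles need at least 3 points")
    seg = np.diff(tr.points, axis=0)
    norms = np.linalg.norm(seg, axis=1)
    u, w = seg[:-1], seg[1:]
    nu, nw = norms[:-1], norms[1:]
    ok = (nu > 0) & (nw > 0)
    if not ok.any():
        raise ValueError("no valid angle: all segments degenerate")
    cosang = np.einsum("ij,ij->i", u[ok], w[ok]) / (nu[ok] * nw[ok])
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(theta.mean()), _pop_sd(theta)


def directional_changes(tr: UniformTrajectory) -> tuple[int, int]:
    """Sign changes of the nonzero per-axis coordinate deltas."""
    if len(tr) < 2:
        raise TooFewPointsError("directional changes need at least 2 points")

    def flips(coord: np.ndarray) -> int:
        d = np.diff(coord)
        d = d[d != 0]
        if len(d) < 2:
            return 0
        return int(np.sum(np.sign(d[1:]) != np.sign(d[:-1])))

    return flips(tr.points[:, 0]), flips(tr.points[:, 1])


def total_distance(tr: UniformTrajectory) -> float:
    """Summed Euclidean distance between consecutive samples, px."""
    if len(tr) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(tr.points, axis=0), axis=1).sum())


def _circle_start_pos(geom: TaskGeometry) -> tuple[float, float, float]:
    c = geom.circle
    x = c["cx"] + c["path_r"] * math.cos(c["theta0"])
    y = c["cy"] + c["path_r"] * math.sin(c["theta0"])
    return x, y, c["circle_r"]


def _work_start_t(s: TaskSession) -> int:
    """Timestamp at which the participant started working on the task."""
    if s.task in (Task.POINT_AND_CLICK, Task.DRAG_AND_DROP, Task.SLIDER):
        for e in s.events:
            if e.kind is EventKind.CLICK_DOWN:
                return e.t
        raise ValueError(f"session {s.key}: no click_down work-start marker")
    # follow_circle: first move sample inside the circle at its start position
    cx, cy, r = _circle_start_pos(s.geometry)
    for e in s.events:
        if e.kind is EventKind.MOVE and math.hypot(e.x - cx, e.y - cy) <= r:
            return e.t
    raise ValueError(f"session {s.key}: cursor never entered the circle")


def time_features(s: TaskSession) -> tuple[float, float]:
    """(task_time_s, working_time_s) from the raw event stream.

    Task time spans the first to the last event on the task page; working
    time starts at the work-start marker (first click for the click
    tasks, first sample inside the pursuit circle otherwise).
    """
    if not s.events:
        raise ValueError("empty session")
    t_first, t_last = s.events[0].t, s.events[-1].t
    t_work = _work_start_t(s)
    return (t_last - t_first) / 1000.0, (t_last - t_work) / 1000.0


def _point_line_distance(
    pts: np.ndarray, a: tuple[float, float], b: tuple[float, float]
) -> np.ndarray:
    """Perpendicular distance of each point to the infinite line a–b.

    Degenerate line (a == b) falls back to the Euclidean distance to a.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    nrm = np.linalg.norm(ab)
    if nrm == 0:
        return np.linalg.norm(pts - a, axis=1)
    # |cross product| / |ab|
    rel = pts - a
    cross = rel[:, 0] * ab[1] - rel[:, 1] * ab[0]
    return np.abs(cross) / nrm


def ideal_line_deviation(
    tr: UniformTrajectory, trials: list[TrialSegment]
) -> tuple[float, float, float]:
    """Deviation of every trial sample from its trial's ideal line.

    Deviations are pooled across all trials of the task before taking
    the total, mean and population SD.
    """
    if not trials:
        raise ValueError("empty trial set")
    devs = []
    for trial in trials:
        if len(trial.indices) == 0:
            continue
        pts = tr.points[trial.indices]
        devs.append(_point_line_distance(pts, trial.start, trial.end))
    if not devs:
        raise ValueError("no trial contains any sample")
    d = np.concatenate(devs)
    return float(d.sum()), float(d.mean()), _pop_sd(d)


def in_circle_ratio(
    tr: UniformTrajectory, geom: TaskGeometry, work_start_t: float
) -> float:
    """Time inside the moving pursuit circle over time outside it.

    Each grid sample from work start onward is classified by whether the
    cursor lies within the circle radius of the (moving) circle center.
    The outside time in the denominator is floored at one sample interval
    to keep the ratio finite for perfect pursuit.
    """
    c = geom.circle
    times = tr.times
    mask = times >= work_start_t
    t_rel = (times[mask] - work_start_t) / 1000.0
    theta = c["theta0"] + c["omega"] * t_rel
    centers = np.column_stack(
        [c["cx"] + c["path_r"] * np.cos(theta), c["cy"] + c["path_r"] * np.sin(theta)]
    )
    dist = np.linalg.norm(tr.points[mask] - centers, axis=1)
    n_in = int(np.sum(dist <= c["circle_r"]))
    n_out = int(np.sum(dist > c["circle_r"]))
    return n_in * tr.dt / max(n_out * tr.dt, tr.dt)


# ---------------------------------------------------------------------------
# Trial segmentation


def _indices_between(tr: UniformTrajectory, t0: float, t1: float) -> np.ndarray:
    times = tr.times
    return np.nonzero((times >= t0) & (times <= t1))[0]


def segment_trials(s: TaskSession, tr: UniformTrajectory) -> list[TrialSegment]:
    """Split a trajectory into trials for the deviation features.

    Point-and-click trials run from click k to click k+1 (the first trial
    from the first move event to the first click).  Drag-and-drop trials
    run from a press to the matching release of a successful drop —
    a release inside the pending target box; a reset (release outside)
    ends no trial.
    """
    if s.task is Task.POINT_AND_CLICK:
        downs = [e for e in s.events if e.kind is EventKind.CLICK_DOWN]
        if not downs:
            return []
        trials = []
        t0 = tr.origin_t
        p0 = tuple(tr.points[0])
        for e in downs:
            idx = _indices_between(tr, t0, e.t)
            trials.append(TrialSegment(start=p0, end=(e.x, e.y), indices=idx))
            t0, p0 = e.t, (e.x, e.y)
        return trials

    if s.task is Task.DRAG_AND_DROP:
        clicks = [e for e in s.events if e.kind is not EventKind.MOVE]
        boxes = s.geometry.trials
        trials = []
        j = 0
        pending_down = None
        for e in clicks:
            if e.kind is EventKind.CLICK_DOWN:
                pending_down = e
            elif e.kind is EventKind.CLICK_UP and pending_down is not None:
                if j < len(boxes):
                    b = boxes[j]
                    inside = (
                        b["box_x"] <= e.x <= b["box_x"] + b["box_w"]
                        and b["box_y"] <= e.y <= b["box_y"] + b["box_h"]
                    )
                else:
                    inside = False
                if inside:
                    idx = _indices_between(tr, pending_down.t, e.t)
                    trials.append(
                        TrialSegment(
                            start=(pending_down.x, pending_down.y),
                            end=(e.x, e.y),
                            indices=idx,
                        )
                    )
                    j += 1
                pending_down = None
        return trials

    raise ValueError(f"no trial segmentation for task {s.task.value}")


def extract_features(s: TaskSession, dt: float = 15.0) -> FeatureVector:
    """Preprocess a session and compute its applicable feature set."""
    cleaned, _ = remove_artifacts(s)
    tr = preprocess_session(s, dt=dt)
    names = TASK_FEATURES[s.task]
    out: dict[str, float] = {}

    task_time, working_time = time_features(cleaned)
    out["task_time_s"] = task_time
    out["working_time_s"] = working_time
    out["speed_mean"], out["speed_sd"] = speed_stats(tr)
    (
        out["acc_pos_mean"],
        out["acc_pos_sd"],
        out["acc_neg_mean"],
        out["acc_neg_sd"],
    ) = acceleration_stats(tr)
    out["dist_total"] = total_distance(tr)
    out["angle_mean"], out["angle_sd"] = angle_stats(tr)
    out["xflips"], out["yflips"] = directional_changes(tr)

    if "dev_total" in names:
        trials = segment_trials(cleaned, tr)
        out["dev_total"], out["dev_mean"], out["dev_sd"] = ideal_line_deviation(
            tr, trials
        )
    if "in_circle_ratio" in names:
        out["in_circle_ratio"] = in_circle_ratio(tr, s.geometry, _work_start_t(cleaned))

    return FeatureVector(task=s.task, values={k: out[k] for k in names})
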