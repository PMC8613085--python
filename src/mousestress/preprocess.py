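"""Pointer-log preprocessing: artifact removal, outlier exclusion, resampling.

The chain mirrors event-based browser capture: consecutive duplicate move
events (same timestamp, or same x and y) are artifacts of the event loop
and are dropped; participants whose task duration exceeds three times the
median are excluded; the surviving move stream is linearly interpolated
onto a uniform 15 ms grid, which every kinematic feature consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortDataset, EventKind, MouseEvent, Stage, Task, TaskSession

__all__ = [
    "UniformTrajectory",
    "remove_artifacts",
    "exclude_outliers",
    "interpolate",
    "preprocess_session",
    "TooFewPointsError",
    "DT_MS",
    "EXCLUSION_FACTOR",
]

#: Resampling interval, milliseconds.
DT_MS = 15
#: Task-duration exclusion threshold, multiples of the median.
EXCLUSION_FACTOR = 3.0


class TooFewPointsError(ValueError):
    """Fewer move events than the operation requires."""


@dataclass
class UniformTrajectory:
    """Positional series resampled onto a uniform time grid.

    ``points`` has shape (n, 2); sample ``i`` sits at time
    ``origin_t + i * dt`` milliseconds.  Click events are carried through
    unchanged for segmentation and rendering.
    """

    dt: float
    origin_t: int
    points: np.ndarray
    clicks: list[MouseEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def times(self) -> np.ndarray:
        return self.origin_t + self.dt * np.arange(len(self.points))


def remove_artifacts(s: TaskSession) -> tuple[TaskSession, int]:
    """Drop duplicate consecutive move events; clicks are never dropped.

    Two move events adjacent in the move stream are duplicates when they
    share a timestamp or share both coordinates; the rule is applied
    iteratively left to right, so a run of duplicates collapses to its
    first member.  Idempotent.
    """
    kept: list[MouseEvent] = []
    last_move: MouseEvent | None = None
    removed = 0
    for e in s.events:
        if e.kind is not EventKind.MOVE:
            kept.append(e)
            continue
        if last_move is not None and (
            e.t == last_move.t or (e.x == last_move.x and e.y == last_move.y)
        ):
            removed += 1
            continue
        kept.append(e)
        last_move = e
    return replace(s, events=kept), removed


def exclude_outliers(
    cohort: CohortDataset, task: Task
) -> tuple[CohortDataset, pd.DataFrame]:
    """Remove a task's duration outliers; returns (filtered cohort, report).

    Within each stage of ``task``, the median task duration is computed
    once over all participants present; any participant whose duration
    strictly exceeds ``EXCLUSION_FACTOR`` times that median is removed
    from the task (both stages, to keep the difference-score design
    balanced).  The report lists pid, task, stage, duration_s, rule.
    """
    task = Task(task)
    rows = []
    excluded_pids: set[str] = set()
    for stage in Stage:
        sessions = cohort.sessions_for(task, stage)
        if len(sessions) < 3:
            continue
        durations = {s.participant_id: s.duration_s for s in sessions}
        med = float(np.median(list(durations.values())))
        for pid, dur in durations.items():
            if dur > EXCLUSION_FACTOR * med:
                excluded_pids.add(pid)
                rows.append(
                    {
                        "pid": pid,
                        "task": task.value,
                        "stage": stage.value,
                        "duration_s": dur,
                        "rule": f"duration > {EXCLUSION_FACTOR:g} x median ({med:.3f} s)",
                    }
                )
    sessions = {
        key: s
        for key, s in cohort.sessions.items()
        if not (key[1] is task and key[0] in excluded_pids)
    }
    report = pd.DataFrame(rows, columns=["pid", "task", "stage", "duration_s", "rule"])
    filtered = CohortDataset(
        sessions=sessions, reports=cohort.reports, provenance=cohort.provenance
    )
    return filtered, report


def interpolate(s: TaskSession, dt: float = DT_MS) -> UniformTrajectory:
    """Linearly resample the move stream onto a uniform ``dt`` grid.

    The grid starts at the first move timestamp and ends at the last one;
    a trailing partial interval is dropped rather than extrapolated.
    Click events pass through untouched.
    """
    t, x, y = s.move_arrays()
    if len(t) < 2:
        raise TooFewPointsError(
            f"session {s.key} has {len(t)} move events; need at least 2"
        )
    origin = t[0]
    n = int(np.floor((t[-1] - origin) / dt)) + 1
    grid = origin + dt * np.arange(n)
    xi = np.interp(grid, t, x)
    yi = np.interp(grid, t, y)
    return UniformTrajectory(
        dt=dt,
        origin_t=int(origin),
        points=np.column_stack([xi, yi]),
        clicks=s.click_events(),
    )


def preprocess_session(s: TaskSession, dt: float = DT_MS) -> UniformTrajectory:
    """Artifact removal followed by uniform resampling."""
    cleaned, _ = remove_artifacts(s)
    return interpolate(cleaned, dt=dt)
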