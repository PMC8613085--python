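"""Domain types and on-disk formats for pointer-event cohorts.

A cohort is a collection of task sessions — one participant working one
mouse task in one experimental stage — plus the per-stage self-reports
(SAM valence/arousal per task, and a twelve-item mood questionnaire with
appended stress and nostalgia items).

On disk a cohort is a JSON-Lines event file (one object per pointer
event) together with a CSV sidecar holding one row per
(participant, task, stage): screen size, task geometry as a JSON blob,
and the self-report columns.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "EventKind",
    "Task",
    "Stage",
    "Condition",
    "MouseEvent",
    "TaskGeometry",
    "TaskSession",
    "SelfReport",
    "CohortDataset",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
    "validate_session",
    "TRIAL_COUNTS",
    "MIN_SCREEN_W",
    "MIN_SCREEN_H",
]


class EventKind(str, Enum):
    MOVE = "move"
    CLICK_DOWN = "click_down"
    CLICK_UP = "click_up"


class Task(str, Enum):
    POINT_AND_CLICK = "point_and_click"
    DRAG_AND_DROP = "drag_and_drop"
    SLIDER = "slider"
    FOLLOW_CIRCLE = "follow_circle"


class Stage(str, Enum):
    BASELINE = "baseline"
    APPLICATION = "application"


class Condition(str, Enum):
    HIGH_STRESS = "high_stress"
    LOW_STRESS = "low_stress"


#: Number of trials each task presents (clicks / drags / slides / pursuit runs).
TRIAL_COUNTS = {
    Task.POINT_AND_CLICK: 17,
    Task.DRAG_AND_DROP: 12,
    Task.SLIDER: 12,
    Task.FOLLOW_CIRCLE: 1,
}

# Minimum display resolution required of participants.
MIN_SCREEN_W = 950
MIN_SCREEN_H = 600

# MDBF-style bipolar subscales: fixed item index sets (0-based into the
# twelve-item vector).  Each subscale is the mean of its four items.
MDBF_SUBSCALES = {
    "good_bad": (0, 3, 6, 9),
    "rest_unrest": (1, 4, 7, 10),
    "alert_tired": (2, 5, 8, 11),
}


@dataclass(slots=True)
class MouseEvent:
    """A single pointer event: positional change or button press/release.

    Coordinates are screen pixels (origin top-left, y downward); ``t`` is
    integer milliseconds since session start.
    """

    kind: EventKind
    x: float
    y: float
    t: int
    extras: dict | None = None

    def __post_init__(self) -> None:
        self.kind = EventKind(self.kind)


@dataclass
class TaskGeometry:
    """Trial targets a task presents, needed for segmentation and scoring.

    ``trials`` holds one dict per trial:

    * point_and_click — ``{"x", "y", "r"}`` circle targets (17)
    * drag_and_drop — ``{"start_x", "start_y", "start_r", "box_x",
      "box_y", "box_w", "box_h"}`` (12)
    * slider — ``{"track_y", "start_x", "target_x", "half_w"}`` (12)
    * follow_circle — one dict with the pursuit-path parameters
      ``{"cx", "cy", "path_r", "circle_r", "omega", "theta0",
      "duration_s"}`` (angular velocity ``omega`` in rad/s; 25 s run)
    """

    task: Task
    trials: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.task = Task(self.task)

    @property
    def circle(self) -> dict:
        if self.task is not Task.FOLLOW_CIRCLE:
            raise ValueError("circle parameters only exist for follow_circle")
        return self.trials[0]

    def to_json(self) -> str:
        return json.dumps({"task": self.task.value, "trials": self.trials})

    @classmethod
    def from_json(cls, blob: str) -> "TaskGeometry":
        d = json.loads(blob)
        return cls(task=Task(d["task"]), trials=d["trials"])


@dataclass
class TaskSession:
    """One participant × task × stage pointer log with its metadata."""

    participant_id: str
    task: Task
    stage: Stage
    condition: Condition
    screen_w: int
    screen_h: int
    events: list[MouseEvent]
    geometry: TaskGeometry

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        self.stage = Stage(self.stage)
        self.condition = Condition(self.condition)

    @property
    def key(self) -> tuple[str, Task, Stage]:
        return (self.participant_id, self.task, self.stage)

    def move_events(self) -> list[MouseEvent]:
        return [e for e in self.events if e.kind is EventKind.MOVE]

    def click_events(self) -> list[MouseEvent]:
        return [e for e in self.events if e.kind is not EventKind.MOVE]

    def move_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(t, x, y) arrays over move events only."""
        mv = self.move_events()
        t = np.array([e.t for e in mv], dtype=float)
        x = np.array([e.x for e in mv], dtype=float)
        y = np.array([e.y for e in mv], dtype=float)
        return t, x, y

    @property
    def duration_s(self) -> float:
        """Task time: last minus first event timestamp, seconds."""
        if not self.events:
            return 0.0
        return (self.events[-1].t - self.events[0].t) / 1000.0


@dataclass
class SelfReport:
    """Self-reported affect for one participant × stage.

    ``sam`` maps each task to its (valence, arousal) rating, both on the
    0–4 scale (valence 0 = positive, 4 = negative; arousal 0 = calm,
    4 = excited).  ``mdbf_items`` are the twelve 0–4 mood items; the
    three bipolar subscales are fixed means of four items each.
    """

    participant_id: str
    stage: Stage
    sam: dict[Task, tuple[float, float]]
    mdbf_items: list[float]
    stress_item: float
    nostalgia_item: float

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        self.sam = {Task(k): (float(v[0]), float(v[1])) for k, v in self.sam.items()}
        if len(self.mdbf_items) != 12:
            raise ValueError("mdbf_items must have exactly 12 entries")

    def subscale(self, name: str) -> float:
        idx = MDBF_SUBSCALES[name]
        return float(np.mean([self.mdbf_items[i] for i in idx]))

    @property
    def good_bad(self) -> float:
        return self.subscale("good_bad")

    @property
    def rest_unrest(self) -> float:
        return self.subscale("rest_unrest")

    @property
    def alert_tired(self) -> float:
        return self.subscale("alert_tired")


@dataclass
class CohortDataset:
    """All sessions and self-reports of one simulated or recorded cohort."""

    sessions: dict[tuple[str, Task, Stage], TaskSession]
    reports: dict[tuple[str, Stage], SelfReport]
    provenance: str = ""

    @property
    def participants(self) -> list[str]:
        return sorted({pid for pid, _, _ in self.sessions})

    def condition_of(self, pid: str) -> Condition:
        for (p, _, _), s in self.sessions.items():
            if p == pid:
                return s.condition
        raise KeyError(pid)

    def sessions_for(self, task: Task, stage: Stage | None = None) -> list[TaskSession]:
        task = Task(task)
        out = []
        for (_, tk, st), s in sorted(self.sessions.items()):
            if tk is task and (stage is None or st is Stage(stage)):
                out.append(s)
        return out

    def incomplete_participants(self) -> list[str]:
        """Participants missing a stage for any task they appear in."""
        bad = set()
        by_pid_task: dict[tuple[str, Task], set[Stage]] = {}
        for pid, task, stage in self.sessions:
            by_pid_task.setdefault((pid, task), set()).add(stage)
        for (pid, _), stages in by_pid_task.items():
            if stages != {Stage.BASELINE, Stage.APPLICATION}:
                bad.add(pid)
        return sorted(bad)


class CohortParseError(ValueError):
    """Malformed cohort file; message names the offending line."""


def validate_session(s: TaskSession) -> list[str]:
    """Check session invariants; returns a list of violation strings.

    An empty list means the session is well formed.  Violations are data,
    not exceptions: downstream stages decide what to do with flagged
    sessions.
    """
    violations: list[str] = []
    for i, e in enumerate(s.events):
        if e.x < 0 or e.y < 0:
            violations.append(f"negative coordinate at event {i}")
            break
    for i in range(1, len(s.events)):
        if s.events[i].t < s.events[i - 1].t:
            violations.append(f"timestamp order violated at event {i}")
    if s.events and s.events[0].t < 0:
        violations.append("negative timestamp at event 0")
    if s.screen_w < MIN_SCREEN_W or s.screen_h < MIN_SCREEN_H:
        violations.append(
            f"screen {s.screen_w}x{s.screen_h} below required "
            f"{MIN_SCREEN_W}x{MIN_SCREEN_H}"
        )
    expected = TRIAL_COUNTS[s.task]
    if len(s.geometry.trials) != expected:
        violations.append(
            f"trial count {len(s.geometry.trials)} != {expected} for {s.task.value}"
        )
    return violations


# ---------------------------------------------------------------------------
# On-disk formats


def _event_record(pid: str, task: Task, stage: Stage, cond: Condition, e: MouseEvent) -> dict:
    rec = {
        "pid": pid,
        "task": task.value,
        "stage": stage.value,
        "cond": cond.value,
        "kind": e.kind.value,
        "x": e.x,
        "y": e.y,
        "t": e.t,
    }
    if e.extras:
        rec["extras"] = e.extras
    return rec


def write_cohort(dataset: CohortDataset, path: str | Path) -> None:
    """Write ``dataset`` as ``<path>.jsonl`` events + ``<path>.csv`` sidecar.

    ``path`` is a stem; the two files round-trip bit-compatibly with
    :func:`read_cohort`.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    jsonl = path.with_suffix(".jsonl")
    sidecar = path.with_suffix(".csv")

    with open(jsonl, "w") as fh:
        for key in sorted(dataset.sessions):
            s = dataset.sessions[key]
            for e in s.events:
                fh.write(
                    json.dumps(
                        _event_record(s.participant_id, s.task, s.stage, s.condition, e)
                    )
                )
                fh.write("\n")

    rows = []
    for key in sorted(dataset.sessions):
        s = dataset.sessions[key]
        rep = dataset.reports.get((s.participant_id, s.stage))
        row = {
            "pid": s.participant_id,
            "task": s.task.value,
            "stage": s.stage.value,
            "cond": s.condition.value,
            "screen_w": s.screen_w,
            "screen_h": s.screen_h,
            "geometry": s.geometry.to_json(),
        }
        if rep is not None:
            val, aro = rep.sam.get(s.task, (math.nan, math.nan))
            row["valence"] = val
            row["arousal"] = aro
            row["mdbf_items"] = json.dumps(rep.mdbf_items)
            row["stress_item"] = rep.stress_item
            row["nostalgia_item"] = rep.nostalgia_item
        rows.append(row)
    pd.DataFrame(rows).to_csv(sidecar, index=False)


def _parse_event_line(line: str, lineno: int) -> dict:
    try:
        rec = json.loads(line)
    except json.JSONDecodeError as exc:
        raise CohortParseError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
    for field_name in ("pid", "task", "stage", "cond", "kind", "x", "y", "t"):
        if field_name not in rec:
            raise CohortParseError(f"line {lineno}: missing field '{field_name}'")
    if rec["kind"] not in {k.value for k in EventKind}:
        raise CohortParseError(f"line {lineno}: unknown event kind '{rec['kind']}'")
    for num_field in ("x", "y", "t"):
        if isinstance(rec[num_field], bool) or not isinstance(rec[num_field], (int, float)):
            raise CohortParseError(
                f"line {lineno}: field '{num_field}' is not numeric "
                f"(got {rec[num_field]!r})"
            )
    return rec


def read_cohort(path: str | Path) -> CohortDataset:
    """Read a cohort written by :func:`write_cohort` and validate it.

    Raises
    ------
    CohortParseError
        Malformed event line (names the line number) or a timestamp
        regression within a session.
    FileNotFoundError
        Missing event or sidecar file.
    """
    path = Path(path)
    jsonl = path.with_suffix(".jsonl")
    sidecar = path.with_suffix(".csv")
    meta = pd.read_csv(sidecar, dtype={"pid": str}, float_precision="round_trip")

    events: dict[tuple[str, Task, Stage], list[MouseEvent]] = {}
    conds: dict[str, Condition] = {}
    with open(jsonl) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            rec = _parse_event_line(line, lineno)
            key = (str(rec["pid"]), Task(rec["task"]), Stage(rec["stage"]))
            ev = MouseEvent(
                kind=EventKind(rec["kind"]),
                x=rec["x"],
                y=rec["y"],
                t=rec["t"],
                extras=rec.get("extras"),
            )
            bucket = events.setdefault(key, [])
            if bucket and ev.t < bucket[-1].t:
                raise CohortParseError(
                    f"line {lineno}: timestamp regression within session {key}"
                )
            bucket.append(ev)
            conds[str(rec["pid"])] = Condition(rec["cond"])

    sessions: dict[tuple[str, Task, Stage], TaskSession] = {}
    reports: dict[tuple[str, Stage], SelfReport] = {}
    for _, row in meta.iterrows():
        key = (str(row["pid"]), Task(row["task"]), Stage(row["stage"]))
        sessions[key] = TaskSession(
            participant_id=key[0],
            task=key[1],
            stage=key[2],
            condition=Condition(row["cond"]),
            screen_w=int(row["screen_w"]),
            screen_h=int(row["screen_h"]),
            events=events.get(key, []),
            geometry=TaskGeometry.from_json(row["geometry"]),
        )
        if "valence" in meta.columns and not pd.isna(row.get("valence", math.nan)):
            rkey = (key[0], key[2])
            if rkey not in reports:
                reports[rkey] = SelfReport(
                    participant_id=key[0],
                    stage=key[2],
                    sam={},
                    mdbf_items=json.loads(row["mdbf_items"]),
                    stress_item=float(row["stress_item"]),
                    nostalgia_item=float(row["nostalgia_item"]),
                )
            reports[rkey].sam[key[1]] = (float(row["valence"]), float(row["arousal"]))

    return CohortDataset(sessions=sessions, reports=reports, provenance=str(path))
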