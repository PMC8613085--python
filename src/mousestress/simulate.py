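"""Synthetic cursor-kinematics and self-report cohort generator.

Emulates event-based browser capture of four goal-directed mouse tasks
performed twice (baseline and application stage) by participants randomly
assigned to a high- or low-stress condition.  Aimed movements follow a
minimum-jerk profile with Fitts'-law durations and signal-dependent
lateral noise (noise SD proportional to instantaneous speed) — the
standard motor-control baseline — optionally followed by one corrective
submovement.  Client-dependent sampling rates span 20–200 Hz with a
median near 60 Hz.

Experimental structure injected into the data:

* a multiplicative practice gain at the application stage (``speed_stage``),
* an optional condition×stage stress effect on movement speed and on
  neuromotor noise (``speed_stress``, ``noise_stress``; both default to
  1.0, i.e. no kinematic stress effect),
* self-reports with a condition×stage interaction calibrated to a target
  partial eta squared (default .015), with the nostalgia item receiving
  no condition effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .cohort import (
    CohortDataset,
    Condition,
    EventKind,
    MouseEvent,
    SelfReport,
    Stage,
    Task,
    TaskGeometry,
    TaskSession,
    TRIAL_COUNTS,
)

__all__ = [
    "SimConfig",
    "MovementParams",
    "EffectParams",
    "fitts_duration",
    "simulate_movement",
    "simulate_task_session",
    "simulate_self_reports",
    "simulate_cohort",
]


def fitts_duration(distance: float, width: float, a: float, b: float) -> float:
    """Fitts'-law movement time a + b*log2(distance/width + 1), seconds."""
    if distance <= 0:
        raise ValueError("degenerate movement: zero distance")
    return a + b * math.log2(distance / width + 1.0)


@dataclass
class MovementParams:
    """Aimed-movement model parameters.

    fitts_a/fitts_b: Fitts'-law intercept (s) and slope (s/bit);
    noise_gamma: lateral noise SD per unit speed (px per px/s);
    p_correction: probability of one corrective submovement.
    """

    fitts_a: float = 0.15
    fitts_b: float = 0.15
    noise_gamma: float = 0.008
    p_correction: float = 0.3


@dataclass
class EffectParams:
    """Injectable experimental effects.

    Multiplicative gains apply at the application stage (``speed_stage``)
    and additionally, for high-stress participants, to speed and noise
    (``speed_stress``, ``noise_stress``).  ``report_interaction_eta2`` is
    the target partial eta squared of the self-report condition×stage
    interaction; ``report_sd`` the rating noise SD.
    """

    speed_stage: float = 1.05
    speed_stress: float = 1.0
    noise_stress: float = 1.0
    report_interaction_eta2: float = 0.015
    report_sd: float = 0.8


@dataclass
class SimConfig:
    """Cohort generator configuration; ``seed`` is mandatory for reruns."""

    n_participants: int = 100
    p_high_stress: float = 480 / 994
    seed: int = 0
    rate_range_hz: tuple[float, float] = (20.0, 200.0)
    screen: tuple[int, int] = (1280, 800)
    movement: MovementParams = field(default_factory=MovementParams)
    effects: EffectParams = field(default_factory=EffectParams)
    tasks: tuple[Task, ...] = tuple(Task)

    def __post_init__(self) -> None:
        self.tasks = tuple(Task(t) for t in self.tasks)
        if not (0.0 <= self.p_high_stress <= 1.0):
            raise ValueError("p_high_stress must lie in [0, 1]")
        lo, hi = self.rate_range_hz
        if not (20.0 <= lo <= hi <= 200.0):
            raise ValueError("rate_range_hz must lie within [20, 200]")
        for name in ("speed_stage", "speed_stress", "noise_stress"):
            if getattr(self.effects, name) <= 0:
                raise ValueError(f"effects.{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("simulation config must state a seed")
        if "movement" in raw:
            raw["movement"] = MovementParams(**raw["movement"])
        if "effects" in raw:
            raw["effects"] = EffectParams(**raw["effects"])
        for key in ("rate_range_hz", "screen", "tasks"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tasks"] = [t.value for t in self.tasks]
        return d


# ---------------------------------------------------------------------------
# Participant-level latent attributes


@dataclass
class _Participant:
    pid: str
    condition: Condition
    rate_hz: float
    skill: float          # multiplicative speed factor
    noise_factor: float   # multiplicative noise factor
    pursuit_lag_s: float
    report_intercepts: np.ndarray  # valence, arousal, stress, nostalgia, 12 mdbf


def _draw_rate(rng: np.random.Generator, lo: float, hi: float) -> float:
    """Client sampling rate: 0.4 point mass at 60 Hz, else log-uniform."""
    if 60.0 >= lo and 60.0 <= hi and rng.random() < 0.4:
        return 60.0
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _make_participant(pid: str, cond: Condition, cfg: SimConfig,
                      rng: np.random.Generator) -> _Participant:
    return _Participant(
        pid=pid,
        condition=cond,
        rate_hz=_draw_rate(rng, *cfg.rate_range_hz),
        skill=float(np.exp(rng.normal(0.0, 0.12))),
        noise_factor=float(np.exp(rng.normal(0.0, 0.2))),
        pursuit_lag_s=float(rng.uniform(0.08, 0.15)),
        report_intercepts=np.clip(rng.normal(2.0, 0.5, size=16), 0.0, 4.0),
    )


def _stage_multipliers(stage: Stage, cond: Condition, cfg: SimConfig) -> tuple[float, float]:
    """(speed multiplier, noise multiplier) for a stage × condition cell."""
    speed, noise = 1.0, 1.0
    if stage is Stage.APPLICATION:
        speed *= cfg.effects.speed_stage
        if cond is Condition.HIGH_STRESS:
            speed *= cfg.effects.speed_stress
            noise *= cfg.effects.noise_stress
    return speed, noise


# ---------------------------------------------------------------------------
# Movement synthesis


def _sample_times(duration_ms: float, rate_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered sample offsets in (0, duration]; the endpoint is always kept."""
    nominal = 1000.0 / rate_hz
    times = []
    t = 0.0
    while True:
        t += nominal * rng.uniform(0.8, 1.2)
        if t >= duration_ms:
            break
        times.append(t)
    times.append(duration_ms)
    return np.asarray(times)


def _min_jerk_points(
    start: np.ndarray,
    target: np.ndarray,
    duration_s: float,
    offsets_ms: np.ndarray,
    noise_sd_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Minimum-jerk positions at the given time offsets plus lateral noise.

    Lateral noise is Gaussian per sample with SD = noise_sd_scale times
    the instantaneous speed, applied perpendicular to the movement axis;
    the profile's terminal speed is zero, so noise vanishes at the
    endpoint and the noiseless path ends exactly on target.
    """
    tau = np.clip(offsets_ms / (duration_s * 1000.0), 0.0, 1.0)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    pts = start[None, :] + (target - start)[None, :] * s[:, None]
    if noise_sd_scale > 0:
        dist = float(np.linalg.norm(target - start))
        speed = dist * (30 * tau**2 - 60 * tau**3 + 30 * tau**4) / duration_s
        axis = (target - start) / dist
        lateral = np.array([-axis[1], axis[0]])
        eps = rng.normal(0.0, 1.0, size=len(tau)) * noise_sd_scale * speed
        pts = pts + eps[:, None] * lateral[None, :]
    return pts


def simulate_movement(
    start,
    target,
    width: float,
    params: MovementParams,
    rng: np.random.Generator,
    *,
    rate_hz: float = 60.0,
    t0: int = 0,
    speed_mult: float = 1.0,
    noise_mult: float = 1.0,
) -> list[MouseEvent]:
    """One aimed movement from ``start`` to ``target`` as move events.

    Duration follows Fitts' law scaled by ``speed_mult``; samples arrive
    at the client rate with ±20% inter-sample jitter; lateral noise SD is
    ``noise_gamma * noise_mult`` per unit speed.  With probability
    ``p_correction`` (and nonzero noise) the main movement lands slightly
    off target and a short corrective submovement finishes the trial.
    """
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    dist = float(np.linalg.norm(target - start))
    if dist == 0:
        raise ValueError("degenerate movement: zero distance")
    duration = fitts_duration(dist, width, params.fitts_a, params.fitts_b) / speed_mult
    gamma = params.noise_gamma * noise_mult

    # Optional corrective submovement: the main movement aims at a point
    # offset from the target by endpoint noise, a second short movement
    # closes the gap.  The offset scales with gamma so the noiseless path
    # still terminates exactly on target.
    legs: list[tuple[np.ndarray, np.ndarray, float]] = []
    if gamma > 0 and rng.random() < params.p_correction:
        offset = rng.normal(0.0, gamma * dist / duration, size=2)
        landing = target + offset
        if np.linalg.norm(offset) >= 1.0:
            d2 = float(np.linalg.norm(target - landing))
            dur2 = fitts_duration(d2, width, params.fitts_a, params.fitts_b / 2) / speed_mult
            legs = [(start, landing, duration), (landing, target, dur2)]
    if not legs:
        legs = [(start, target, duration)]

    events: list[MouseEvent] = []
    leg_t0 = float(t0)
    for a, b, dur in legs:
        offsets = _sample_times(dur * 1000.0, rate_hz, rng)
        pts = _min_jerk_points(a, b, dur, offsets, gamma, rng)
        prev_t = events[-1].t if events else t0 - 1
        for off, (x, y) in zip(offsets, pts):
            t = int(round(leg_t0 + off))
            t = max(t, prev_t + 1)
            events.append(MouseEvent(kind=EventKind.MOVE, x=round(x), y=round(y), t=t))
            prev_t = t
        leg_t0 = events[-1].t
    # pin the endpoint exactly on target (terminal noise is zero anyway)
    events[-1].x = round(float(target[0]))
    events[-1].y = round(float(target[1]))
    return events


# ---------------------------------------------------------------------------
# Task geometry


def _field(cfg: SimConfig) -> tuple[float, float, float, float]:
    """Centered playing field (x0, y0, w, h) on the screen."""
    w, h = 900.0, 550.0
    sx, sy = cfg.screen
    return (sx - w) / 2.0, (sy - h) / 2.0, w, h


def _make_geometry(task: Task, cfg: SimConfig, rng: np.random.Generator) -> TaskGeometry:
    x0, y0, w, h = _field(cfg)
    m = 50.0  # target margin inside the field
    if task is Task.POINT_AND_CLICK:
        trials = [
            {
                "x": float(round(rng.uniform(x0 + m, x0 + w - m))),
                "y": float(round(rng.uniform(y0 + m, y0 + h - m))),
                "r": 15.0,
            }
            for _ in range(TRIAL_COUNTS[task])
        ]
    elif task is Task.DRAG_AND_DROP:
        corners = [
            (x0 + 10, y0 + 10),
            (x0 + w - 70, y0 + 10),
            (x0 + 10, y0 + h - 70),
            (x0 + w - 70, y0 + h - 70),
        ]
        trials = []
        for _ in range(TRIAL_COUNTS[task]):
            bx, by = corners[rng.integers(4)]
            trials.append(
                {
                    "start_x": x0 + w / 2,
                    "start_y": y0 + h / 2,
                    "start_r": 20.0,
                    "box_x": bx,
                    "box_y": by,
                    "box_w": 60.0,
                    "box_h": 60.0,
                }
            )
    elif task is Task.SLIDER:
        trials = [
            {
                "track_y": y0 + h / 2,
                "start_x": x0 + m,
                "target_x": float(round(rng.uniform(x0 + m + 150, x0 + w - m))),
                "half_w": 20.0,
            }
            for _ in range(TRIAL_COUNTS[task])
        ]
    elif task is Task.FOLLOW_CIRCLE:
        trials = [
            {
                "cx": x0 + w / 2,
                "cy": y0 + h / 2,
                "path_r": 150.0,
                "circle_r": 30.0,
                "omega": 2 * math.pi / 25.0,
                "theta0": 0.0,
                "duration_s": 25.0,
            }
        ]
    else:  # pragma: no cover
        raise ValueError(f"unknown task {task}")
    return TaskGeometry(task=task, trials=trials)


# ---------------------------------------------------------------------------
# Session synthesis


def _click_pair(
    x: float, y: float, t: int, rng: np.random.Generator, hold_ms: tuple[int, int] = (60, 140)
) -> tuple[list[MouseEvent], int]:
    t_up = t + int(rng.integers(*hold_ms))
    return (
        [
            MouseEvent(kind=EventKind.CLICK_DOWN, x=round(x), y=round(y), t=t),
            MouseEvent(kind=EventKind.CLICK_UP, x=round(x), y=round(y), t=t_up),
        ],
        t_up,
    )


def _pause(rng: np.random.Generator) -> int:
    """Reaction delay before the next movement, ms (no events emitted)."""
    return int(rng.integers(150, 400))


def _simulate_point_and_click(
    geom, part, speed, noise, params, rng
) -> list[MouseEvent]:
    events: list[MouseEvent] = []
    cx = geom.trials[0]["x"] - 120.0  # entry point near first target
    cy = geom.trials[0]["y"] + 90.0
    pos = np.array([cx, cy])
    t = 0
    events.append(MouseEvent(kind=EventKind.MOVE, x=round(pos[0]), y=round(pos[1]), t=t))
    for trial in geom.trials:
        tgt = np.array([trial["x"], trial["y"]])
        mv = simulate_movement(
            pos, tgt, 2 * trial["r"], params, rng,
            rate_hz=part.rate_hz, t0=t + _pause(rng),
            speed_mult=speed * part.skill, noise_mult=noise * part.noise_factor,
        )
        events.extend(mv)
        clicks, t = _click_pair(mv[-1].x, mv[-1].y, mv[-1].t + int(rng.integers(30, 90)), rng)
        events.extend(clicks)
        pos = np.array([float(mv[-1].x), float(mv[-1].y)])
    return events


def _simulate_drag_and_drop(
    geom, part, speed, noise, params, rng, p_reset: float = 0.05
) -> list[MouseEvent]:
    events: list[MouseEvent] = []
    first = geom.trials[0]
    pos = np.array([first["start_x"] - 150.0, first["start_y"] + 100.0])
    t = 0
    events.append(MouseEvent(kind=EventKind.MOVE, x=round(pos[0]), y=round(pos[1]), t=t))
    for trial in geom.trials:
        start = np.array([trial["start_x"], trial["start_y"]])
        box_c = np.array(
            [trial["box_x"] + trial["box_w"] / 2, trial["box_y"] + trial["box_h"] / 2]
        )
        done = False
        while not done:
            # approach the circle at the field center
            mv = simulate_movement(
                pos, start, 2 * trial["start_r"], params, rng,
                rate_hz=part.rate_hz, t0=t + _pause(rng),
                speed_mult=speed * part.skill, noise_mult=noise * part.noise_factor,
            )
            events.extend(mv)
            t = mv[-1].t + int(rng.integers(30, 90))
            down = MouseEvent(kind=EventKind.CLICK_DOWN, x=mv[-1].x, y=mv[-1].y, t=t)
            events.append(down)
            miss = rng.random() < p_reset
            if miss:
                # drop just outside the box: position resets to center
                drop = box_c + np.array([trial["box_w"], trial["box_h"]]) * 0.9
            else:
                drop = box_c
            mv2 = simulate_movement(
                np.array([float(down.x), float(down.y)]), drop,
                trial["box_w"], params, rng,
                rate_hz=part.rate_hz, t0=t + int(rng.integers(40, 100)),
                speed_mult=speed * part.skill, noise_mult=noise * part.noise_factor,
            )
            events.extend(mv2)
            t = mv2[-1].t + int(rng.integers(30, 90))
            up = MouseEvent(kind=EventKind.CLICK_UP, x=mv2[-1].x, y=mv2[-1].y, t=t)
            events.append(up)
            pos = np.array([float(up.x), float(up.y)])
            done = not miss
    return events


def _simulate_slider(geom, part, speed, noise, params, rng) -> list[MouseEvent]:
    events: list[MouseEvent] = []
    first = geom.trials[0]
    pos = np.array([first["start_x"] + 200.0, first["track_y"] - 120.0])
    t = 0
    events.append(MouseEvent(kind=EventKind.MOVE, x=round(pos[0]), y=round(pos[1]), t=t))
    for trial in geom.trials:
        handle = np.array([trial["start_x"], trial["track_y"]])
        target = np.array([trial["target_x"], trial["track_y"]])
        mv = simulate_movement(
            pos, handle, 2 * trial["half_w"], params, rng,
            rate_hz=part.rate_hz, t0=t + _pause(rng),
            speed_mult=speed * part.skill, noise_mult=noise * part.noise_factor,
        )
        events.extend(mv)
        t = mv[-1].t + int(rng.integers(30, 90))
        events.append(MouseEvent(kind=EventKind.CLICK_DOWN, x=mv[-1].x, y=mv[-1].y, t=t))
        mv2 = simulate_movement(
            np.array([float(mv[-1].x), float(mv[-1].y)]), target,
            2 * trial["half_w"], params, rng,
            rate_hz=part.rate_hz, t0=t + int(rng.integers(40, 100)),
            speed_mult=speed * part.skill, noise_mult=noise * part.noise_factor,
        )
        events.extend(mv2)
        t = mv2[-1].t + int(rng.integers(30, 90))
        events.append(MouseEvent(kind=EventKind.CLICK_UP, x=mv2[-1].x, y=mv2[-1].y, t=t))
        pos = np.array([float(mv2[-1].x), float(mv2[-1].y)])
    return events


def _simulate_follow_circle(geom, part, speed, noise, params, rng) -> list[MouseEvent]:
    c = geom.circle
    start_pos = np.array(
        [c["cx"] + c["path_r"] * math.cos(c["theta0"]),
         c["cy"] + c["path_r"] * math.sin(c["theta0"])]
    )
    pos = np.array([c["cx"], c["cy"] + 30.0])  # cursor begins near field center
    events: list[MouseEvent] = [
        MouseEvent(kind=EventKind.MOVE, x=round(pos[0]), y=round(pos[1]), t=0)
    ]
    mv = simulate_movement(
        pos, start_pos, c["circle_r"], params, rng,
        rate_hz=part.rate_hz, t0=_pause(rng),
        speed_mult=speed * part.skill, noise_mult=noise * part.noise_factor,
    )
    # the circle starts moving the moment the cursor first enters it:
    # truncate the approach there so the 25 s pursuit window is exact
    entry = next(
        i for i, e in enumerate(mv)
        if math.hypot(e.x - start_pos[0], e.y - start_pos[1]) <= c["circle_r"]
    )
    mv = mv[: entry + 1]
    events.extend(mv)
    t_work = mv[-1].t
    duration_ms = c["duration_s"] * 1000.0
    offsets = _sample_times(duration_ms, part.rate_hz, rng)
    lag = part.pursuit_lag_s
    # smooth tracking error: AR(1) per axis, stationary SD scaled by the
    # participant noise factor and the stress noise multiplier
    phi = 0.95
    target_sd = 14.0 * part.noise_factor * noise
    innov_sd = target_sd * math.sqrt(1.0 - phi**2)
    err = rng.normal(0.0, target_sd, size=2)
    prev_t = t_work
    for off in offsets:
        t_rel = off / 1000.0
        theta = c["theta0"] + c["omega"] * max(t_rel - lag, 0.0)
        err = phi * err + rng.normal(0.0, innov_sd, size=2)
        x = c["cx"] + c["path_r"] * math.cos(theta) + err[0]
        y = c["cy"] + c["path_r"] * math.sin(theta) + err[1]
        t = max(int(round(t_work + off)), prev_t + 1)
        events.append(MouseEvent(kind=EventKind.MOVE, x=round(x), y=round(y), t=t))
        prev_t = t
    # final sample lands exactly at t_work + 25 000 ms
    events[-1].t = int(t_work + duration_ms)
    return events


def simulate_task_session(
    pid: str,
    task: Task,
    stage: Stage,
    condition: Condition,
    cfg: SimConfig,
    rng: np.random.Generator,
    participant: _Participant | None = None,
    geometry: TaskGeometry | None = None,
) -> TaskSession:
    """Generate one participant × task × stage session.

    Pass ``geometry`` to reuse one fixed trial layout — the study design
    keeps each task identical across stages and conditions so that task
    differences cannot confound condition effects.
    """
    task, stage, condition = Task(task), Stage(stage), Condition(condition)
    part = participant or _make_participant(pid, condition, cfg, rng)
    speed, noise = _stage_multipliers(stage, condition, cfg)
    geom = geometry or _make_geometry(task, cfg, rng)
    sim = {
        Task.POINT_AND_CLICK: _simulate_point_and_click,
        Task.DRAG_AND_DROP: _simulate_drag_and_drop,
        Task.SLIDER: _simulate_slider,
        Task.FOLLOW_CIRCLE: _simulate_follow_circle,
    }[task]
    events = sim(geom, part, speed, noise, cfg.movement, rng)
    sw, sh = cfg.screen
    for e in events:
        e.x = min(max(e.x, 0), sw - 1)
        e.y = min(max(e.y, 0), sh - 1)
    return TaskSession(
        participant_id=pid,
        task=task,
        stage=stage,
        condition=condition,
        screen_w=sw,
        screen_h=sh,
        events=events,
        geometry=geom,
    )


# ---------------------------------------------------------------------------
# Self-reports


def interaction_shift(eta2: float, sd: float) -> float:
    """Mean shift giving an expected interaction partial eta squared.

    From the balanced two-group difference-score design: the interaction
    F is the squared pooled t on difference scores d (variance 2*sd^2),
    with noncentrality N*delta^2/(8*sd^2); solving
    eta2 = lambda/(lambda + N) gives delta = 2*sqrt(2)*sd*
    sqrt(eta2/(1-eta2)), independent of N.
    """
    if not (0.0 <= eta2 < 1.0):
        raise ValueError("eta2 must lie in [0, 1)")
    return 2.0 * math.sqrt(2.0) * sd * math.sqrt(eta2 / (1.0 - eta2))


# stage (practice/strain) main-effect shifts at the application stage
_STAGE_SHIFT = {"valence": 0.15, "arousal": 0.2, "stress": 0.2, "mdbf": -0.1}


def simulate_self_reports(
    pid: str,
    stage: Stage,
    condition: Condition,
    cfg: SimConfig,
    rng: np.random.Generator,
    participant: _Participant | None = None,
) -> SelfReport:
    """Generate the SAM and mood-questionnaire ratings for one stage.

    Ratings are participant intercept + stage main effect + the
    condition×stage shift (high-stress participants at the application
    stage only) + Gaussian noise, clipped to the 0–4 scale.  The
    interaction shift is calibrated so the expected mixed-ANOVA
    interaction partial eta squared equals ``report_interaction_eta2``;
    the nostalgia item receives no condition effect.
    """
    stage, condition = Stage(stage), Condition(condition)
    part = participant or _make_participant(pid, condition, cfg, rng)
    eff = cfg.effects
    delta = interaction_shift(eff.report_interaction_eta2, eff.report_sd)
    is_app = stage is Stage.APPLICATION
    hit = is_app and condition is Condition.HIGH_STRESS

    def rating(intercept: float, stage_shift: float, cond_shift: float) -> float:
        val = (
            intercept
            + (stage_shift if is_app else 0.0)
            + (cond_shift if hit else 0.0)
            + rng.normal(0.0, eff.report_sd)
        )
        return float(np.clip(val, 0.0, 4.0))

    ic = part.report_intercepts
    sam = {
        task: (
            rating(ic[0], _STAGE_SHIFT["valence"], delta),
            rating(ic[1], _STAGE_SHIFT["arousal"], delta),
        )
        for task in Task
    }
    mdbf = [rating(ic[4 + i], _STAGE_SHIFT["mdbf"], -delta / 2) for i in range(12)]
    return SelfReport(
        participant_id=pid,
        stage=stage,
        sam=sam,
        mdbf_items=mdbf,
        stress_item=rating(ic[2], _STAGE_SHIFT["stress"], delta),
        nostalgia_item=rating(ic[3], 0.0, 0.0),
    )


# ---------------------------------------------------------------------------
# Cohort assembly


def simulate_cohort(cfg: SimConfig) -> CohortDataset:
    """Generate a full cohort: all configured tasks × both stages + reports.

    Deterministic in ``cfg.seed``: per-participant random streams are
    spawned from the master seed, so the dataset is byte-identical on
    rerun.
    """
    if cfg.n_participants < 4:
        raise ValueError("need at least 4 participants")
    master = np.random.SeedSequence(cfg.seed)
    assign_ss, geom_ss = master.spawn(2)
    assign_rng = np.random.default_rng(assign_ss)
    # one fixed trial layout per task: identical across participants,
    # stages and conditions, as in the study design
    geom_rng = np.random.default_rng(geom_ss)
    geoms = {task: _make_geometry(task, cfg, geom_rng) for task in cfg.tasks}
    sessions: dict = {}
    reports: dict = {}
    child_seeds = master.spawn(cfg.n_participants)
    for i in range(cfg.n_participants):
        pid = f"p{i:04d}"
        cond = (
            Condition.HIGH_STRESS
            if assign_rng.random() < cfg.p_high_stress
            else Condition.LOW_STRESS
        )
        prng = np.random.default_rng(child_seeds[i])
        part = _make_participant(pid, cond, cfg, prng)
        for stage in Stage:
            for task in cfg.tasks:
                s = simulate_task_session(
                    pid, task, stage, cond, cfg, prng, part, geometry=geoms[task]
                )
                sessions[s.key] = s
            reports[(pid, stage)] = simulate_self_reports(
                pid, stage, cond, cfg, prng, part
            )
    return CohortDataset(
        sessions=sessions, reports=reports, provenance=f"simulated(seed={cfg.seed})"
    )
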