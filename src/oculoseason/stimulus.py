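"""Stimulus schedules for the three oculomotor tasks.

Three tasks are presented on a monitor 60 cm from a chin rest, with gaze
recorded monocularly at 1,000 Hz:

* **smooth pursuit** — a target moves at constant speed around a circle,
  visible for ~1.5 s per cycle with 0.5 s breaks, 35 cycles;
* **visually-guided saccades** — a target steps instantaneously between
  ten unique horizontal positions, 78 jumps, peripheral dwell 1.5 s and
  central dwell 2.0 s;
* **anti-saccade** — a central fixation dot (1–4 s) alternates with 1 s
  peripheral cues, 18 cues balanced left/right; the subject must saccade to
  the mirror position of the cue.

Coordinates are degrees of visual angle with origin at screen centre,
+x right, +y up; all times are in milliseconds from trial start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SAMPLE_RATE_HZ = 1000.0
VIEWING_DISTANCE_CM = 60.0

SEGMENT_KINDS = ("pursuit_on", "gap", "step_target", "central_fixation", "peripheral_cue")

#: default horizontal target set for the visually-guided task (deg).
#: Symmetric eccentricities at 2.5 deg steps, the centre counted once, and one
#: extra eccentricity to reach ten unique values.
DEFAULT_VGS_POSITIONS = (-10.0, -7.5, -5.0, -2.5, 0.0, 2.5, 5.0, 7.5, 10.0, 12.5)

DEFAULT_PURSUIT_RADIUS_DEG = 8.0
#: phase speed of the pursuit target in deg of arc phase per second; at the
#: default 8 deg radius this is a linear target speed of ~16.8 deg/s.
DEFAULT_PURSUIT_PHASE_SPEED = 120.0
DEFAULT_CUE_ECCENTRICITY_DEG = 8.0

SCREEN_HALF_EXTENT_DEG = 20.0  # generous bound for a monitor at 60 cm


@dataclass(frozen=True)
class TargetSegment:
    """One timed piece of a task: a target position (or gap) with on/offset."""

    onset_ms: float
    offset_ms: float
    x_deg: float
    y_deg: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.offset_ms > self.onset_ms:
            raise ValueError("segment offset must exceed onset")
        if not (np.isfinite(self.x_deg) and np.isfinite(self.y_deg)):
            raise ValueError("target position must be finite")
        if max(abs(self.x_deg), abs(self.y_deg)) > SCREEN_HALF_EXTENT_DEG:
            raise ValueError("target position outside screen bounds")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class TaskSchedule:
    """An ordered, contiguous sequence of target segments for one task.

    For the pursuit task the target position varies *within* ``pursuit_on``
    segments; ``target_position`` evaluates the circular parametrisation with
    phase accumulated over cumulative on-time (the phase is continuous across
    gaps, so the target reappears where it vanished).
    """

    task: str  # {"pursuit", "visually_guided", "antisaccade"}
    segments: tuple[TargetSegment, ...]
    viewing_distance_cm: float = VIEWING_DISTANCE_CM
    sample_rate_hz: float = SAMPLE_RATE_HZ
    pursuit_radius_deg: float | None = None
    pursuit_phase_speed_deg_s: float | None = None

    def __post_init__(self) -> None:
        if self.task not in ("pursuit", "visually_guided", "antisaccade"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.viewing_distance_cm <= 0:
            raise ValueError("viewing distance must be positive")
        for a, b in zip(self.segments, self.segments[1:]):
            if not np.isclose(a.offset_ms, b.onset_ms):
                raise ValueError("segments must be contiguous and non-overlapping")

    @property
    def duration_ms(self) -> float:
        return self.segments[-1].offset_ms if self.segments else 0.0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms * self.sample_rate_hz / 1000.0))

    # -- pursuit circle parametrisation -------------------------------------

    def _pursuit_phase_deg(self, t_ms: np.ndarray) -> np.ndarray:
        """Phase (deg) at times ``t_ms``, accumulating only during on-time."""
        speed = self.pursuit_phase_speed_deg_s
        if speed is None:
            raise ValueError("schedule has no pursuit parametrisation")
        on_time_s = np.zeros_like(np.asarray(t_ms, dtype=float))
        t = np.asarray(t_ms, dtype=float)
        for seg in self.segments:
            if seg.kind != "pursuit_on":
                continue
            inside = np.clip(t - seg.onset_ms, 0.0, seg.duration_ms)
            on_time_s += inside / 1000.0
        return speed * on_time_s

    def target_position(self, t_ms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Target (x, y) in deg at times ``t_ms``; NaN where no target is shown."""
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        x = np.full(t.shape, np.nan)
        y = np.full(t.shape, np.nan)
        if self.task == "pursuit":
            r = self.pursuit_radius_deg
            phase = np.deg2rad(self._pursuit_phase_deg(t))
            on = np.zeros(t.shape, dtype=bool)
            for seg in self.segments:
                if seg.kind == "pursuit_on":
                    on |= (t >= seg.onset_ms) & (t < seg.offset_ms)
            x[on] = r * np.cos(phase[on])
            y[on] = r * np.sin(phase[on])
            return x, y
        for seg in self.segments:
            sel = (t >= seg.onset_ms) & (t < seg.offset_ms)
            x[sel] = seg.x_deg
            y[sel] = seg.y_deg
        return x, y

    def target_velocity(self, t_ms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Target velocity (deg/s); zero for stepped tasks, NaN during gaps."""
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        vx = np.zeros(t.shape)
        vy = np.zeros(t.shape)
        if self.task != "pursuit":
            return vx, vy
        vx[:] = np.nan
        vy[:] = np.nan
        r = self.pursuit_radius_deg
        omega = np.deg2rad(self.pursuit_phase_speed_deg_s)  # rad/s
        phase = np.deg2rad(self._pursuit_phase_deg(t))
        for seg in self.segments:
            if seg.kind != "pursuit_on":
                continue
            sel = (t >= seg.onset_ms) & (t < seg.offset_ms)
            vx[sel] = -r * omega * np.sin(phase[sel])
            vy[sel] = r * omega * np.cos(phase[sel])
        return vx, vy

    @property
    def pursuit_target_speed_deg_s(self) -> float:
        """Constant linear speed of the pursuit target along its circle."""
        if self.task != "pursuit":
            raise ValueError("not a pursuit schedule")
        return self.pursuit_radius_deg * np.deg2rad(self.pursuit_phase_speed_deg_s)


def make_pursuit_schedule(
    n_cycles: int = 35,
    on_duration_s: float = 1.5,
    gap_s: float = 0.5,
    radius_deg: float = DEFAULT_PURSUIT_RADIUS_DEG,
    angular_speed_deg_s: float = DEFAULT_PURSUIT_PHASE_SPEED,
) -> TaskSchedule:
    """Smooth-pursuit schedule: ``n_cycles`` alternating on/gap periods.

    The target traverses a circle of ``radius_deg`` at constant speed;
    ``angular_speed_deg_s`` is the phase speed in deg/s of arc.  Phase is
    frozen during gaps so the trajectory is continuous across cycles.
    """
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    if n_cycles > 0 and (on_duration_s <= 0 or gap_s <= 0):
        raise ValueError("durations must be positive")
    if radius_deg <= 0 or angular_speed_deg_s <= 0:
        raise ValueError("radius and angular speed must be positive")
    segments: list[TargetSegment] = []
    t = 0.0
    on_ms = on_duration_s * 1000.0
    gap_ms = gap_s * 1000.0
    phase = 0.0
    for _ in range(n_cycles):
        x = radius_deg * np.cos(np.deg2rad(phase))
        y = radius_deg * np.sin(np.deg2rad(phase))
        segments.append(TargetSegment(t, t + on_ms, x, y, "pursuit_on"))
        t += on_ms
        phase += angular_speed_deg_s * on_duration_s
        segments.append(TargetSegment(t, t + gap_ms, 0.0, 0.0, "gap"))
        t += gap_ms
    return TaskSchedule(
        task="pursuit",
        segments=tuple(segments),
        pursuit_radius_deg=radius_deg,
        pursuit_phase_speed_deg_s=angular_speed_deg_s,
    )


def make_visually_guided_schedule(
    positions_deg: Sequence[float] | None = None,
    n_jumps: int = 78,
    peripheral_dwell_s: float = 1.5,
    central_dwell_s: float = 2.0,
    seed: int = 0,
) -> TaskSchedule:
    """Visually-guided saccade schedule: ``n_jumps`` instantaneous steps.

    Targets move only horizontally between the unique ``positions_deg``
    (default: ten positions).  Central (0 deg) targets dwell
    ``central_dwell_s``; peripheral targets dwell ``peripheral_dwell_s``.
    The position sequence is deterministic given ``seed``; every listed
    position is visited at least once whenever ``n_jumps >= len(positions)``,
    and consecutive segments always differ in position.
    """
    positions = tuple(dict.fromkeys(DEFAULT_VGS_POSITIONS if positions_deg is None else positions_deg))
    if n_jumps < 0:
        raise ValueError("n_jumps must be >= 0")
    if len(positions) < 2 and n_jumps > 0:
        raise ValueError("need at least 2 unique positions to jump between")
    if peripheral_dwell_s <= 0 or central_dwell_s <= 0:
        raise ValueError("dwell times must be positive")
    rng = np.random.default_rng(seed)
    pos = np.asarray(positions, dtype=float)
    n_seg = n_jumps + 1
    seq: list[float] = []
    if n_seg >= len(pos):
        # a leading permutation guarantees coverage and distinct neighbours
        seq.extend(pos[rng.permutation(len(pos))])
    while len(seq) < n_seg:
        prev = seq[-1] if seq else None
        choices = pos if prev is None else pos[pos != prev]
        seq.append(float(rng.choice(choices)))
    seq = seq[:n_seg]
    segments: list[TargetSegment] = []
    t = 0.0
    for x in seq:
        dwell_ms = (central_dwell_s if x == 0.0 else peripheral_dwell_s) * 1000.0
        segments.append(TargetSegment(t, t + dwell_ms, float(x), 0.0, "step_target"))
        t += dwell_ms
    return TaskSchedule(task="visually_guided", segments=tuple(segments))


def make_antisaccade_schedule(
    n_peripheral: int = 18,
    cue_duration_s: float = 1.0,
    fixation_choices_s: Iterable[float] = (1.0, 2.0, 3.0, 4.0),
    seed: int = 0,
    cue_eccentricity_deg: float = DEFAULT_CUE_ECCENTRICITY_DEG,
) -> TaskSchedule:
    """Anti-saccade schedule: central fixations alternating with 1 s cues.

    ``n_peripheral`` cues (must be even, half on each side, order shuffled by
    ``seed``); each preceding central fixation lasts a duration drawn from
    ``fixation_choices_s`` (default 1–4 s), deterministically given ``seed``.
    """
    if n_peripheral < 0 or n_peripheral % 2 != 0:
        raise ValueError("n_peripheral must be even (left/right balance)")
    if cue_duration_s <= 0:
        raise ValueError("cue duration must be positive")
    choices = np.asarray(sorted(fixation_choices_s), dtype=float)
    if choices.size == 0 or np.any(choices <= 0):
        raise ValueError("fixation durations must be positive")
    rng = np.random.default_rng(seed)
    sides = np.concatenate([np.ones(n_peripheral // 2), -np.ones(n_peripheral // 2)])
    sides = sides[rng.permutation(n_peripheral)] if n_peripheral else sides
    fix_durs = rng.choice(choices, size=n_peripheral) if n_peripheral else np.empty(0)
    segments: list[TargetSegment] = []
    t = 0.0
    for side, fix_s in zip(sides, fix_durs):
        fix_ms = fix_s * 1000.0
        segments.append(TargetSegment(t, t + fix_ms, 0.0, 0.0, "central_fixation"))
        t += fix_ms
        cue_ms = cue_duration_s * 1000.0
        segments.append(
            TargetSegment(t, t + cue_ms, float(side) * cue_eccentricity_deg, 0.0, "peripheral_cue")
        )
        t += cue_ms
    return TaskSchedule(task="antisaccade", segments=tuple(segments))


def make_schedule(task: str, seed: int = 0) -> TaskSchedule:
    """Default schedule for ``task`` in {'pursuit','visually_guided','antisaccade'}."""
    if task == "pursuit":
        return make_pursuit_schedule()
    if task in ("visually_guided", "vgs"):
        return make_visually_guided_schedule(seed=seed)
    if task in ("antisaccade", "anti"):
        return make_antisaccade_schedule(seed=seed)
    raise ValueError(f"unknown task {task!r}")


# -- serialization ----------------------------------------------------------

def schedule_to_frame(schedule: TaskSchedule) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_ms": [s.onset_ms for s in schedule.segments],
            "offset_ms": [s.offset_ms for s in schedule.segments],
            "x_deg": [s.x_deg for s in schedule.segments],
            "y_deg": [s.y_deg for s in schedule.segments],
            "kind": [s.kind for s in schedule.segments],
        }
    )


def write_schedule_csv(schedule: TaskSchedule, path) -> None:
    """Write segments as CSV; pursuit circle parameters go in '#' header lines."""
    with open(path, "w") as fh:
        fh.write(f"# task={schedule.task}\n")
        if schedule.task == "pursuit":
            fh.write(f"# pursuit_radius_deg={schedule.pursuit_radius_deg}\n")
            fh.write(f"# pursuit_phase_speed_deg_s={schedule.pursuit_phase_speed_deg_s}\n")
        schedule_to_frame(schedule).to_csv(fh, index=False)


def read_schedule_csv(path) -> TaskSchedule:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    segments = tuple(
        TargetSegment(r.onset_ms, r.offset_ms, r.x_deg, r.y_deg, r.kind)
        for r in df.itertuples()
    )
    task = meta.get("task", "visually_guided")
    kwargs = {}
    if task == "pursuit":
        kwargs["pursuit_radius_deg"] = float(meta["pursuit_radius_deg"])
        kwargs["pursuit_phase_speed_deg_s"] = float(meta["pursuit_phase_speed_deg_s"])
    return TaskSchedule(task=task, segments=segments, **kwargs)
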