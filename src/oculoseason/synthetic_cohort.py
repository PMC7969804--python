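"""Synthetic gaze traces and a synthetic longitudinal cohort.

The study's raw data are not deposited, so every downstream stage is
exercised against simulations that share the statistical structure the
analysis assumes:

* ``simulate_trace`` renders a 1,000 Hz monocular gaze trace for one task
  schedule from a set of subject-specific oculomotor parameters
  (:class:`SubjectParams`), together with a ground-truth event log that
  serves as the oracle for detector and feature tests.
* ``simulate_cohort`` generates a cohort of subjects followed over up to
  four sessions (pre-, early-, late- and post-season).  A season-linked
  latent impairment jointly shifts the oculomotor parameters, ONSD and the
  ImPACT composites; subjects additionally carry stable random offsets in
  all outcomes.

Saccades follow a raised-cosine-family velocity profile
``v(t) ∝ sin(pi*t/D)**shape`` whose exponent sets the Q-ratio
(peak velocity x duration / amplitude): shape 0 is a rectangular profile
(Q=1), shape 2 a raised cosine (Q=2); the default is chosen so Q ≈ 1.6,
a typical physiological value.  Saccade duration obeys a linear main
sequence ``duration = intercept + slope * amplitude``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln

from .stimulus import (
    DEFAULT_PURSUIT_PHASE_SPEED,
    DEFAULT_PURSUIT_RADIUS_DEG,
    TaskSchedule,
    make_antisaccade_schedule,
    make_pursuit_schedule,
    make_visually_guided_schedule,
)

MS = 1000.0  # samples per second == samples per 1000 ms at 1 kHz


def q_ratio_of_shape(shape: float) -> float:
    """Q-ratio of the ``sin**shape`` velocity-profile family.

    Q(s) = sqrt(pi) * Gamma(s/2 + 1) / Gamma((s+1)/2); Q(0)=1 (rectangular),
    Q(2)=2 (raised cosine).
    """
    s = float(shape)
    return math.sqrt(math.pi) * math.exp(gammaln(s / 2.0 + 1.0) - gammaln((s + 1.0) / 2.0))


def shape_for_q(q: float) -> float:
    """Inverse of :func:`q_ratio_of_shape` (valid for 1 < q < ~2.5)."""
    return brentq(lambda s: q_ratio_of_shape(s) - q, 1e-9, 10.0)


#: profile exponent giving the physiological default Q-ratio of 1.6
DEFAULT_VEL_SHAPE = shape_for_q(1.6)


@dataclass
class SubjectParams:
    """Ground-truth oculomotor parameters of one simulated subject-session."""

    subject_id: str = "s0"
    latency_mean_ms: float = 200.0
    latency_sd_ms: float = 30.0
    ms_slope_ms_per_deg: float = 2.5
    ms_intercept_ms: float = 20.0
    vel_shape: float = DEFAULT_VEL_SHAPE
    pursuit_gain: float = 0.92
    antisaccade_error_p: float = 0.25
    premature_rate: float = 0.10  # events per second of fixation
    landing_noise_deg: float = 0.5
    gaze_noise_deg: float = 0.05  # video-oculography RMS noise

    def validate(self) -> None:
        if not 0.0 <= self.antisaccade_error_p <= 1.0:
            raise ValueError("antisaccade_error_p must be in [0, 1]")
        if self.pursuit_gain < 0:
            raise ValueError("pursuit_gain must be >= 0")
        if self.ms_slope_ms_per_deg <= 0:
            raise ValueError("main-sequence slope must be positive")
        for name in ("latency_sd_ms", "landing_noise_deg", "gaze_noise_deg",
                     "premature_rate", "latency_mean_ms", "ms_intercept_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.vel_shape < 0:
            raise ValueError("vel_shape must be >= 0")


@dataclass
class GazeTrace:
    """Uniformly sampled monocular gaze positions at 1 kHz."""

    task: str
    time_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    valid: np.ndarray
    subject_id: str = "s0"
    session: int = 1

    @property
    def n(self) -> int:
        return self.time_ms.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.time_ms, "x_deg": self.x_deg,
             "y_deg": self.y_deg, "valid": self.valid.astype(int)}
        )

    def mirrored(self) -> "GazeTrace":
        return replace(self, x_deg=-self.x_deg)


LOG_COLUMNS = [
    "kind", "onset_ms", "offset_ms", "amplitude_deg", "peak_velocity_deg_s",
    "x0", "y0", "x1", "y1", "segment_index", "cue_index", "is_error",
]


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame(columns=LOG_COLUMNS)


class _EyeBuilder:
    """Incrementally writes an eye-position trajectory onto a 1 kHz grid."""

    def __init__(self, n: int, params: SubjectParams, rng: np.random.Generator):
        self.n = n
        self.x = np.zeros(n)
        self.y = np.zeros(n)
        self.params = params
        self.rng = rng
        self.cursor = 0  # next sample to write
        self.pos = (0.0, 0.0)
        self.events: list[dict] = []

    def hold(self, until_ms: float) -> None:
        i = min(self.n, int(round(until_ms)))
        if i > self.cursor:
            self.x[self.cursor:i] = self.pos[0]
            self.y[self.cursor:i] = self.pos[1]
            self.cursor = i

    def saccade_to(self, t_ms: float, target: tuple[float, float], kind: str,
                   segment_index: int = -1, cue_index=np.nan, is_error=np.nan,
                   landing_noise: float | None = None) -> dict | None:
        """Inject a main-sequence saccade starting at ``t_ms`` toward ``target``.

        Returns the logged event (or None if it would not fit in the trace).
        """
        p = self.params
        t0 = int(round(t_ms))
        if t0 < self.cursor:
            t0 = self.cursor
        noise = p.landing_noise_deg if landing_noise is None else landing_noise
        end = (target[0] + self.rng.normal(0.0, noise),
               target[1] + self.rng.normal(0.0, noise))
        self.hold(t0)
        dx = end[0] - self.pos[0]
        dy = end[1] - self.pos[1]
        amp = math.hypot(dx, dy)
        if amp < 1e-9:
            return None
        dur_ms = p.ms_intercept_ms + p.ms_slope_ms_per_deg * amp
        n_samp = max(2, int(round(dur_ms)))
        if t0 + n_samp >= self.n:
            return None
        u = (np.arange(n_samp) + 0.5) / n_samp
        v = np.sin(np.pi * u) ** p.vel_shape
        disp = np.cumsum(v)
        disp /= disp[-1]
        self.x[t0:t0 + n_samp] = self.pos[0] + dx * disp
        self.y[t0:t0 + n_samp] = self.pos[1] + dy * disp
        self.cursor = t0 + n_samp
        self.pos = end
        peak_vel = q_ratio_of_shape(p.vel_shape) * amp / (n_samp / MS)
        ev = {
            "kind": kind, "onset_ms": float(t0), "offset_ms": float(t0 + n_samp),
            "amplitude_deg": amp, "peak_velocity_deg_s": peak_vel,
            "x0": end[0] - dx, "y0": end[1] - dy, "x1": end[0], "y1": end[1],
            "segment_index": segment_index, "cue_index": cue_index,
            "is_error": is_error,
        }
        self.events.append(ev)
        return ev

    def finish(self) -> None:
        self.hold(self.n)


def _draw_latency(rng: np.random.Generator, p: SubjectParams, floor: float = 100.0) -> float:
    return max(floor, rng.normal(p.latency_mean_ms, p.latency_sd_ms))


def _simulate_vgs(schedule: TaskSchedule, p: SubjectParams, rng: np.random.Generator,
                  eye: _EyeBuilder) -> None:
    segs = schedule.segments
    # assume fixation on the first target has been acquired before trial start
    eye.pos = (segs[0].x_deg, segs[0].y_deg)
    for k in range(1, len(segs)):
        seg = segs[k]
        jump_t = seg.onset_ms
        target = (seg.x_deg, seg.y_deg)
        t_resp = jump_t + _draw_latency(rng, p)
        # occasional anticipatory saccade in the first 80 ms after the jump
        if rng.random() < min(0.5, p.premature_rate * seg.duration_ms / MS):
            t_pre = jump_t + rng.uniform(5.0, 70.0)
            amp = rng.uniform(2.0, 3.0) * rng.choice((-1.0, 1.0))
            pre = eye.saccade_to(t_pre, (eye.pos[0] + amp, eye.pos[1]),
                                 "premature", segment_index=k,
                                 landing_noise=0.2 * p.landing_noise_deg)
            if pre is not None:
                t_resp = max(t_resp, pre["offset_ms"] + 30.0)
        if t_resp >= seg.offset_ms - 10.0:
            continue  # no response before the next jump: missed step
        eye.saccade_to(t_resp, target, "response", segment_index=k)


def _simulate_pursuit(schedule: TaskSchedule, p: SubjectParams, rng: np.random.Generator,
                      eye: _EyeBuilder, catchup_threshold_deg: float = 1.5,
                      catchup_latency_ms: float = 125.0) -> None:
    t_grid = np.arange(eye.n, dtype=float)
    tx, ty = schedule.target_position(t_grid)
    first = True
    for k, seg in enumerate(schedule.segments):
        if seg.kind != "pursuit_on":
            continue  # gaps: builder holds position by default
        i0 = int(round(seg.onset_ms))
        i1 = min(eye.n, int(round(seg.offset_ms)))
        eye.hold(i0)  # fill the preceding gap with the held position
        if first:
            # initial foveation of the target after a reaction time
            t_sac = seg.onset_ms + _draw_latency(rng, p)
            eye.saccade_to(t_sac, (seg.x_deg, seg.y_deg), "response", segment_index=k)
            first = False
        i = max(i0, eye.cursor)
        while i < i1:
            # smooth tracking at `pursuit_gain` from the current eye position
            p0x, p0y = eye.pos
            gx = p0x + p.pursuit_gain * (tx[i:i1] - tx[i])
            gy = p0y + p.pursuit_gain * (ty[i:i1] - ty[i])
            err = np.hypot(tx[i:i1] - gx, ty[i:i1] - gy)
            over = np.nonzero(err > catchup_threshold_deg)[0]
            stop = i1 if over.size == 0 else i + int(over[0])
            eye.x[i:stop] = gx[: stop - i]
            eye.y[i:stop] = gy[: stop - i]
            if stop > i:
                eye.pos = (float(gx[stop - i - 1]), float(gy[stop - i - 1]))
                eye.cursor = stop
            if stop >= i1:
                break
            # positional error exceeded threshold: catch-up saccade after a
            # short latency, aimed at the target's position at landing time
            t_sac = stop + catchup_latency_ms
            if t_sac >= i1 - 5:
                # keep tracking until the cycle ends
                i = stop
                p0x, p0y = eye.pos
                gx = p0x + p.pursuit_gain * (tx[i:i1] - tx[i])
                gy = p0y + p.pursuit_gain * (ty[i:i1] - ty[i])
                eye.x[i:i1] = gx
                eye.y[i:i1] = gy
                eye.pos = (float(gx[-1]), float(gy[-1])) if i1 > i else eye.pos
                eye.cursor = i1
                break
            # track during the latency period
            i_lat = int(round(t_sac))
            p0x, p0y = eye.pos
            gx = p0x + p.pursuit_gain * (tx[stop:i_lat] - tx[stop])
            gy = p0y + p.pursuit_gain * (ty[stop:i_lat] - ty[stop])
            eye.x[stop:i_lat] = gx
            eye.y[stop:i_lat] = gy
            if i_lat > stop:
                eye.pos = (float(gx[-1]), float(gy[-1]))
                eye.cursor = i_lat
            # aim at the target position anticipated for landing time
            amp0 = math.hypot(tx[i_lat] - eye.pos[0], ty[i_lat] - eye.pos[1])
            dur0 = p.ms_intercept_ms + p.ms_slope_ms_per_deg * amp0
            j = min(i1 - 1, i_lat + int(round(dur0)))
            ev = eye.saccade_to(i_lat, (float(tx[j]), float(ty[j])), "catchup",
                                segment_index=k,
                                landing_noise=0.3 * p.landing_noise_deg)
            i = eye.cursor


def _simulate_antisaccade(schedule: TaskSchedule, p: SubjectParams,
                          rng: np.random.Generator, eye: _EyeBuilder) -> None:
    cue_index = -1
    for k, seg in enumerate(schedule.segments):
        if seg.kind == "central_fixation":
            # return to centre from wherever the previous trial ended
            if math.hypot(*eye.pos) > 0.5 and k > 0:
                eye.saccade_to(seg.onset_ms + _draw_latency(rng, p, floor=120.0),
                               (0.0, 0.0), "return", segment_index=k,
                               landing_noise=0.3 * p.landing_noise_deg)
            # premature fixation breaks: Poisson during the remaining fixation
            t_free = eye.cursor
            window_ms = max(0.0, seg.offset_ms - 150.0 - t_free)
            n_pre = rng.poisson(p.premature_rate * window_ms / MS)
            times = np.sort(rng.uniform(t_free, t_free + window_ms, size=n_pre))
            for t_pre in times:
                if t_pre < eye.cursor:
                    continue
                amp = rng.uniform(2.5, 3.5) * rng.choice((-1.0, 1.0))
                ev = eye.saccade_to(t_pre, (amp, 0.0), "premature",
                                    segment_index=k,
                                    landing_noise=0.2 * p.landing_noise_deg)
                if ev is not None and ev["offset_ms"] + 220.0 < seg.offset_ms - 80.0:
                    eye.saccade_to(ev["offset_ms"] + rng.uniform(150.0, 220.0),
                                   (0.0, 0.0), "return", segment_index=k,
                                   landing_noise=0.2 * p.landing_noise_deg)
        elif seg.kind == "peripheral_cue":
            cue_index += 1
            is_error = bool(rng.random() < p.antisaccade_error_p)
            goal_x = seg.x_deg if is_error else -seg.x_deg
            t_resp = seg.onset_ms + _draw_latency(rng, p, floor=120.0)
            ev = eye.saccade_to(t_resp, (goal_x, seg.y_deg), "response",
                                segment_index=k, cue_index=cue_index,
                                is_error=is_error)
            if ev is not None and is_error:
                # corrective saccade to the instructed mirror location
                eye.saccade_to(ev["offset_ms"] + rng.uniform(120.0, 200.0),
                               (-seg.x_deg, seg.y_deg), "correction",
                               segment_index=k, cue_index=cue_index)


def _insert_blinks(trace_valid: np.ndarray, log: pd.DataFrame, n: int,
                   blink_interval_ms: float, blink_duration_ms: float) -> list[tuple[int, int]]:
    """Mark one ~150 ms invalid gap per ~30 s, avoiding logged events.

    Returns the blink intervals actually placed.
    """
    if n < blink_interval_ms:
        return []
    onsets = np.asarray(log["onset_ms"], dtype=float) if len(log) else np.empty(0)
    offsets = np.asarray(log["offset_ms"], dtype=float) if len(log) else np.empty(0)
    placed = []
    half = blink_duration_ms / 2.0
    guard = 80.0  # clearance between a blink and any true event
    for centre in np.arange(blink_interval_ms, n - half, blink_interval_ms):
        ok = None
        for shift in np.arange(0.0, 2000.0, 50.0):
            for c in (centre + shift, centre - shift):
                a, b = c - half - guard, c + half + guard
                if a < 0 or b >= n:
                    continue
                if np.any((onsets < b) & (offsets > a)):
                    continue
                ok = c
                break
            if ok is not None:
                break
        if ok is not None:
            a, b = int(round(ok - half)), int(round(ok + half))
            trace_valid[a:b] = False
            placed.append((a, b))
    return placed


def simulate_trace(schedule: TaskSchedule, params: SubjectParams, seed: int = 0,
                   blink_interval_s: float = 30.0, blink_duration_ms: float = 150.0,
                   ) -> tuple[GazeTrace, pd.DataFrame]:
    """Simulate one 1 kHz gaze trace for ``schedule`` and log all injected events.

    Returns ``(trace, log)`` where the log is a DataFrame with one row per
    injected saccade (kinds: response, catchup, premature, return,
    correction), carrying onset/offset, amplitude, analytic peak velocity,
    endpoints and — for anti-saccade responses — the cue index and the
    direction-error flag.
    """
    params.validate()
    n = schedule.n_samples
    if n == 0:
        trace = GazeTrace(schedule.task, np.empty(0), np.empty(0), np.empty(0),
                          np.empty(0, dtype=bool), params.subject_id)
        return trace, _empty_log()
    rng = np.random.default_rng(seed)
    eye = _EyeBuilder(n, params, rng)
    if schedule.task == "visually_guided":
        _simulate_vgs(schedule, params, rng, eye)
    elif schedule.task == "pursuit":
        _simulate_pursuit(schedule, params, rng, eye)
    elif schedule.task == "antisaccade":
        _simulate_antisaccade(schedule, params, rng, eye)
    else:  # pragma: no cover
        raise ValueError(f"unknown task {schedule.task!r}")
    eye.finish()
    log = pd.DataFrame(eye.events, columns=LOG_COLUMNS) if eye.events else _empty_log()
    valid = np.ones(n, dtype=bool)
    _insert_blinks(valid, log, n, blink_interval_s * MS, blink_duration_ms)
    x = eye.x
    y = eye.y
    if params.gaze_noise_deg > 0:
        x = x + rng.normal(0.0, params.gaze_noise_deg, size=n)
        y = y + rng.normal(0.0, params.gaze_noise_deg, size=n)
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    trace = GazeTrace(schedule.task, np.arange(n, dtype=float), x, y, valid,
                      params.subject_id)
    return trace, log


# ---------------------------------------------------------------------------
# Longitudinal cohort
# ---------------------------------------------------------------------------

IMPACT_COMPOSITES = ["verbal", "visual", "visual_motor", "reaction_time",
                     "impulse_control", "symptom"]

#: population mean, between-subject SD, residual SD and per-unit-latent shift
#: for each ImPACT composite (points; reaction_time in seconds).  Shifts are
#: signed so that impairment worsens the score in its native direction.
DEFAULT_COMPOSITE_MODEL: dict[str, tuple[float, float, float, float]] = {
    "verbal": (85.0, 8.0, 3.0, -6.0),
    "visual": (75.0, 9.0, 3.5, -6.0),
    "visual_motor": (38.0, 5.0, 2.0, -3.0),
    "reaction_time": (0.60, 0.05, 0.02, +0.05),
    "impulse_control": (6.0, 2.5, 1.5, +2.0),
    "symptom": (5.0, 3.0, 2.0, +2.0),
}

#: correlation of each composite's subject offset with the shared cognitive
#: ability factor (drives the dominant first PC of the composites)
COMPOSITE_G_LOADING = {
    "verbal": 0.85, "visual": 0.85, "visual_motor": 0.85, "reaction_time": -0.85,
    "impulse_control": -0.15, "symptom": -0.15,
}

#: additive shift of each oculomotor parameter per unit of latent impairment
DEFAULT_PARAM_SHIFTS: dict[str, float] = {
    "latency_mean_ms": +25.0,
    "latency_sd_ms": +8.0,
    "ms_slope_ms_per_deg": +0.4,
    "pursuit_gain": -0.08,
    "antisaccade_error_p": +0.10,
    "premature_rate": +0.40,
    "landing_noise_deg": +0.15,
}

#: between-subject SDs of the baseline oculomotor parameters
DEFAULT_PARAM_SUBJECT_SD: dict[str, float] = {
    "latency_mean_ms": 20.0,
    "ms_slope_ms_per_deg": 0.3,
    "ms_intercept_ms": 3.0,
    "pursuit_gain": 0.04,
    "antisaccade_error_p": 0.10,
    "premature_rate": 0.05,
    "landing_noise_deg": 0.10,
}


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic longitudinal cohort.

    The defaults emulate the study conditions: 30 subjects with complete
    data over four sessions (pre/early/late/post season), ONSD around
    4 mm at baseline rising late in the season, and a latent impairment
    profile that peaks late-season and jointly shifts the oculomotor
    parameters and the ImPACT composites.
    """

    n_subjects: int = 30
    sessions_per_subject: int = 4
    seed: int = 0
    #: latent impairment per session (unitless; scales all parameter and
    #: composite shifts)
    latent_profile: tuple[float, ...] = (0.0, 0.2, 1.0, 0.6)
    #: additive ONSD shift per session, mm
    onsd_session_shift_mm: tuple[float, ...] = (0.0, 0.1, 0.5, 0.3)
    onsd_mean_mm: float = 4.0
    subject_outcome_sd: float = 0.4  # between-subject ONSD intercept SD, mm
    residual_sd: float = 0.15  # within-subject ONSD noise SD, mm
    composite_model: dict = field(default_factory=lambda: dict(DEFAULT_COMPOSITE_MODEL))
    param_shifts: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_SHIFTS))
    param_subject_sd: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_SUBJECT_SD))
    #: "traces": simulate gaze traces and run the full detection/feature
    #: pipeline; "analytic": draw feature vectors from their sampling
    #: distributions (fast); "outcomes": outcomes table only
    mode: str = "traces"

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.sessions_per_subject < 1:
            raise ValueError("sessions_per_subject must be >= 1")
        if self.sessions_per_subject > 4:
            raise ValueError("at most 4 sessions are modelled")
        if len(self.latent_profile) < self.sessions_per_subject:
            raise ValueError("latent_profile shorter than number of sessions")
        if len(self.onsd_session_shift_mm) < self.sessions_per_subject:
            raise ValueError("onsd_session_shift_mm shorter than number of sessions")
        if self.mode not in ("traces", "analytic", "outcomes"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class CohortDataset:
    """Outcome table plus (optionally) per-session oculomotor features."""

    outcomes: pd.DataFrame  # subject_id, session, onsd_mm, six composites
    features: pd.DataFrame | None  # subject_id, session, feature columns
    params: dict  # (subject_id, session) -> SubjectParams
    config: CohortConfig


def _subject_params(base_seed_rng: np.random.Generator, subject_id: str,
                    config: CohortConfig) -> SubjectParams:
    p = SubjectParams(subject_id=subject_id)
    for name, sd in config.param_subject_sd.items():
        setattr(p, name, getattr(p, name) + base_seed_rng.normal(0.0, sd))
    p.latency_mean_ms = max(120.0, p.latency_mean_ms)
    p.ms_slope_ms_per_deg = max(1.0, p.ms_slope_ms_per_deg)
    p.ms_intercept_ms = max(10.0, p.ms_intercept_ms)
    p.pursuit_gain = float(np.clip(p.pursuit_gain, 0.5, 1.0))
    p.antisaccade_error_p = float(np.clip(p.antisaccade_error_p, 0.02, 0.9))
    p.premature_rate = max(0.01, p.premature_rate)
    p.landing_noise_deg = max(0.1, p.landing_noise_deg)
    return p


def _shift_params(p: SubjectParams, latent: float, shifts: dict) -> SubjectParams:
    q = replace(p)
    for name, delta in shifts.items():
        setattr(q, name, getattr(q, name) + latent * delta)
    q.pursuit_gain = float(np.clip(q.pursuit_gain, 0.05, 1.0))
    q.antisaccade_error_p = float(np.clip(q.antisaccade_error_p, 0.0, 1.0))
    q.premature_rate = max(0.0, q.premature_rate)
    q.latency_sd_ms = max(0.0, q.latency_sd_ms)
    return q


def simulate_cohort(config: CohortConfig | None = None) -> CohortDataset:
    """Generate the synthetic cohort defined by ``config``.

    Deterministic given ``config.seed``: every subject/session draws from a
    counter-derived substream, so the content of any one session does not
    depend on evaluation order.
    """
    config = config or CohortConfig()
    config.validate()
    root = np.random.SeedSequence(config.seed)
    subj_seeds = root.spawn(config.n_subjects)
    out_rows = []
    feat_rows = []
    params_map: dict[tuple[str, int], SubjectParams] = {}
    for i in range(config.n_subjects):
        sid = f"S{i:02d}"
        streams = subj_seeds[i].spawn(config.sessions_per_subject + 1)
        srng = np.random.default_rng(streams[0])
        base = _subject_params(srng, sid, config)
        u_onsd = srng.normal(0.0, config.subject_outcome_sd)
        g = srng.normal(0.0, 1.0)  # shared cognitive ability factor
        comp_idio = {c: srng.normal(0.0, 1.0) for c in IMPACT_COMPOSITES}
        for s in range(1, config.sessions_per_subject + 1):
            rng = np.random.default_rng(streams[s])
            latent = config.latent_profile[s - 1]
            p_s = _shift_params(base, latent, config.param_shifts)
            params_map[(sid, s)] = p_s
            row = {"subject_id": sid, "session": s}
            row["onsd_mm"] = (config.onsd_mean_mm + u_onsd
                              + config.onsd_session_shift_mm[s - 1]
                              + rng.normal(0.0, config.residual_sd))
            for c in IMPACT_COMPOSITES:
                mu, subj_sd, resid_sd, shift = config.composite_model[c]
                rho = COMPOSITE_G_LOADING[c]
                subj_off = subj_sd * (rho * g + math.sqrt(1 - rho * rho) * comp_idio[c])
                val = mu + subj_off + latent * shift + rng.normal(0.0, resid_sd)
                if c in ("impulse_control", "symptom"):
                    val = max(0.5, val)
                elif c == "reaction_time":
                    val = max(0.2, val)
                row[c] = val
            out_rows.append(row)
            if config.mode == "analytic":
                feat = _analytic_features(p_s, rng)
            elif config.mode == "traces":
                feat = _trace_features(p_s, int(rng.integers(2**31 - 1)))
            else:
                feat = None
            if feat is not None:
                feat_rows.append({"subject_id": sid, "session": s, **feat})
    outcomes = pd.DataFrame(out_rows)
    features = pd.DataFrame(feat_rows) if feat_rows else None
    if features is not None:
        features = features[["subject_id", "session"]
                            + [c for c in features.columns if c not in ("subject_id", "session")]]
    return CohortDataset(outcomes=outcomes, features=features, params=params_map,
                         config=config)


def _trace_features(p: SubjectParams, seed: int) -> dict:
    """Full-pipeline features: simulate all three tasks, detect, aggregate."""
    from .gaze_events import detect_saccades, preprocess
    from .oculo_features import extract_session_features

    schedules = {
        "visually_guided": make_visually_guided_schedule(seed=seed % 1009),
        "pursuit": make_pursuit_schedule(),
        "antisaccade": make_antisaccade_schedule(seed=seed % 2003),
    }
    traces = {}
    for j, (task, sched) in enumerate(schedules.items()):
        trace, _ = simulate_trace(sched, p, seed=seed + 17 * (j + 1))
        traces[task] = trace
    return extract_session_features(traces, schedules).to_dict()


def _analytic_features(p: SubjectParams, rng: np.random.Generator) -> dict:
    """Draw a feature vector from its approximate sampling distribution.

    A fast stand-in for the full trace pipeline: each feature is centred on
    the value implied by ``p`` with sampling noise at roughly the standard
    error the real extraction would have (medians over ~78 steps, counts
    over the trial, etc.).  Feature names match the trace pipeline registry.
    """
    from .oculo_features import FEATURE_NAMES  # noqa: F401  (kept in sync by test)

    q = q_ratio_of_shape(p.vel_shape)
    n_steps = 78.0
    se_med = 1.2533 / math.sqrt(n_steps)
    lat = p.latency_mean_ms
    d: dict[str, float] = {}
    d["vgs_reaction_time_med"] = lat + rng.normal(0, p.latency_sd_ms * se_med)
    d["vgs_reaction_time_sd"] = abs(p.latency_sd_ms * (1 + rng.normal(0, 0.08)))
    land_med = p.landing_noise_deg * 1.1774  # Rayleigh median
    d["vgs_landing_error_med"] = land_med * (1 + rng.normal(0, 0.09))
    d["vgs_landing_error_sd"] = p.landing_noise_deg * 0.65 * (1 + rng.normal(0, 0.1))
    ttf = lat + p.ms_intercept_ms + p.ms_slope_ms_per_deg * 4.0
    d["vgs_time_to_fixate_med"] = ttf + rng.normal(0, p.latency_sd_ms * se_med)
    d["vgs_time_to_fixate_sd"] = abs(p.latency_sd_ms * 1.1 * (1 + rng.normal(0, 0.1)))
    d["vgs_q_ratio_med"] = q * (1 + rng.normal(0, 0.005))
    d["vgs_q_ratio_sd"] = 0.05 * q * (1 + rng.normal(0, 0.1))
    d["vgs_peak_mean_ratio_med"] = q * (1 + rng.normal(0, 0.005))
    d["vgs_peak_mean_ratio_sd"] = 0.05 * q * (1 + rng.normal(0, 0.1))
    n_pre_vgs = rng.poisson(min(0.5, p.premature_rate * 1.6) * n_steps)
    d["vgs_premature_total"] = float(n_pre_vgs)
    d["vgs_premature_sd"] = math.sqrt(max(0.05, n_pre_vgs / n_steps))
    d["vgs_main_sequence_slope"] = p.ms_slope_ms_per_deg * (1 + rng.normal(0, 0.02))
    disp = 0.005 + 0.25 * p.gaze_noise_deg
    d["vgs_fixation_dispersion_med"] = disp * (1 + rng.normal(0, 0.05))
    d["vgs_fixation_dispersion_sd"] = 0.5 * disp * (1 + rng.normal(0, 0.2))
    # pursuit
    d["sp_gain_med"] = p.pursuit_gain + rng.normal(0, 0.01)
    d["sp_gain_sd"] = abs(0.03 + rng.normal(0, 0.008))
    speed = DEFAULT_PURSUIT_RADIUS_DEG * math.radians(DEFAULT_PURSUIT_PHASE_SPEED)
    # error growth / effective threshold (incl. drift during catch-up latency)
    exp_catchup = (1 - p.pursuit_gain) * speed * 52.5 / 1.95
    n_cu = rng.poisson(max(1.0, exp_catchup))
    d["sp_catchup_total"] = float(n_cu)
    d["sp_catchup_sd"] = math.sqrt(max(0.05, n_cu / 35.0))
    # catch-up amplitudes span too little range to pin the slope down well
    d["sp_main_sequence_slope"] = p.ms_slope_ms_per_deg + rng.normal(0, 1.5)
    # anti-saccade
    n_err = rng.binomial(18, p.antisaccade_error_p)
    d["as_error_total"] = float(n_err)
    d["as_error_sd"] = math.sqrt(max(0.01, (n_err / 18.0) * (1 - n_err / 18.0)))
    n_pre_as = rng.poisson(p.premature_rate * 45.0)
    d["as_premature_total"] = float(n_pre_as)
    d["as_premature_sd"] = math.sqrt(max(0.05, n_pre_as / 18.0))
    d["as_reaction_time_med"] = lat + rng.normal(0, p.latency_sd_ms * 0.35)
    d["as_reaction_time_sd"] = abs(p.latency_sd_ms * 1.15 * (1 + rng.normal(0, 0.12)))
    d["as_main_sequence_slope"] = p.ms_slope_ms_per_deg * (1 + rng.normal(0, 0.05))
    d["as_fixation_dispersion_med"] = disp * (1 + rng.normal(0, 0.05))
    d["as_fixation_dispersion_sd"] = 0.5 * disp * (1 + rng.normal(0, 0.2))
    return d


def cohort_to_csv(dataset: CohortDataset, out_dir) -> None:
    """Write outcome (and feature) tables as CSV into ``out_dir``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    cols = ["subject_id", "session", "onsd_mm"] + IMPACT_COMPOSITES
    dataset.outcomes[cols].to_csv(os.path.join(out_dir, "outcomes.csv"), index=False)
    if dataset.features is not None:
        dataset.features.to_csv(os.path.join(out_dir, "features.csv"), index=False)
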