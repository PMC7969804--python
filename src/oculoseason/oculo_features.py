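"""Per-task oculomotor metrics and the per-session feature vector.

Each task yields trial-level metrics (one row per target step, pursuit cycle
or cue).  A session's feature vector summarises every continuous metric by
its **median** (central channel) and **standard deviation** (dispersion
channel) across trials, and every event metric by its **total count** and the
SD of per-trial counts — separating a shift in typical performance from an
increase in performance variability.  Each task additionally contributes a
main-sequence slope (least-squares fit of saccade duration on amplitude) and,
for the stepped tasks, fixation dispersion.

Missing trials (no response before the next target step, fully masked cycle)
are recorded as NaN and flagged, never silently zeroed; imputation happens
only inside the modelling stage, from training folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze_events import CleanTrace, DetectionResult, SaccadeEvent
from .stimulus import TaskSchedule

#: anticipatory cutoff: a saccade launched earlier than this after a target
#: step cannot be a response to it (standard oculomotor convention)
ANTICIPATION_CUTOFF_MS = 80.0
FIXATION_RADIUS_DEG = 2.0
FIXATION_HOLD_MS = 100.0
MIN_RESPONSE_AMP_DEG = 1.0


def _registry() -> list[dict]:
    reg: list[dict] = []

    def cont(task, base):
        reg.append(dict(name=f"{task}_{base}_med", task=task, base=base, channel="central"))
        reg.append(dict(name=f"{task}_{base}_sd", task=task, base=base, channel="dispersion"))

    def count(task, base):
        reg.append(dict(name=f"{task}_{base}_total", task=task, base=base, channel="central"))
        reg.append(dict(name=f"{task}_{base}_sd", task=task, base=base, channel="dispersion"))

    for base in ("reaction_time", "landing_error", "time_to_fixate", "q_ratio",
                 "peak_mean_ratio"):
        cont("vgs", base)
    count("vgs", "premature")
    reg.append(dict(name="vgs_main_sequence_slope", task="vgs",
                    base="main_sequence_slope", channel="central"))
    cont("vgs", "fixation_dispersion")
    cont("sp", "gain")
    count("sp", "catchup")
    reg.append(dict(name="sp_main_sequence_slope", task="sp",
                    base="main_sequence_slope", channel="central"))
    count("as", "error")
    count("as", "premature")
    cont("as", "reaction_time")
    reg.append(dict(name="as_main_sequence_slope", task="as",
                    base="main_sequence_slope", channel="central"))
    cont("as", "fixation_dispersion")
    return reg


FEATURE_REGISTRY: list[dict] = _registry()
FEATURE_NAMES: list[str] = [f["name"] for f in FEATURE_REGISTRY]
FEATURE_CHANNEL: dict[str, str] = {f["name"]: f["channel"] for f in FEATURE_REGISTRY}
FEATURE_TASK: dict[str, str] = {f["name"]: f["task"] for f in FEATURE_REGISTRY}


def main_sequence_slope(saccades: list[SaccadeEvent],
                        min_amplitude: float = MIN_RESPONSE_AMP_DEG) -> float:
    """Least-squares slope of duration (ms) on amplitude (deg)."""
    amps = np.array([s.amplitude_deg for s in saccades])
    durs = np.array([s.duration_ms for s in saccades])
    sel = amps >= min_amplitude
    if sel.sum() < 3 or np.ptp(amps[sel]) < 1e-9:
        return float("nan")
    return float(np.polyfit(amps[sel], durs[sel], 1)[0])


def compute_saccade_task_metrics(clean: CleanTrace, schedule: TaskSchedule,
                                 detection: DetectionResult) -> pd.DataFrame:
    """Per-step metrics for the visually-guided task.

    For each target jump, the first detected saccade of amplitude >= 1 deg
    launched at least 80 ms after the jump is the response; its onset defines
    the reaction time and its endpoint the landing error.  Earlier (>=1 deg)
    saccades in the first 80 ms are counted premature.  ``time_to_fixate`` is
    the delay until gaze stays within 2 deg of the target for 100 ms.
    """
    if schedule.task != "visually_guided":
        raise ValueError("expected a visually-guided schedule")
    sac = detection.saccades
    onsets = np.array([s.onset_ms for s in sac])
    amps = np.array([s.amplitude_deg for s in sac])
    rows = []
    segs = schedule.segments
    t0 = float(clean.time_ms[0]) if clean.time_ms.size else 0.0
    for k in range(1, len(segs)):
        seg = segs[k]
        jump = seg.onset_ms
        nxt = seg.offset_ms
        row = dict(step=k, reaction_time_ms=np.nan, landing_error_deg=np.nan,
                   time_to_fixate_ms=np.nan, q_ratio=np.nan,
                   peak_mean_ratio=np.nan, premature_count=0, missing=True)
        in_win = (onsets >= jump) & (onsets < nxt) & (amps >= MIN_RESPONSE_AMP_DEG)
        idx = np.nonzero(in_win)[0]
        row["premature_count"] = int(np.sum(onsets[idx] - jump < ANTICIPATION_CUTOFF_MS))
        resp = [i for i in idx if onsets[i] - jump >= ANTICIPATION_CUTOFF_MS]
        if resp:
            ev = sac[resp[0]]
            row["reaction_time_ms"] = ev.onset_ms - jump
            row["landing_error_deg"] = math.hypot(ev.x1 - seg.x_deg, ev.y1 - seg.y_deg)
            row["q_ratio"] = ev.q_ratio
            row["peak_mean_ratio"] = ev.peak_mean_ratio
            row["missing"] = False
        # time to fixate: first 100 ms stretch within 2 deg of the target
        a = int(jump - t0)
        b = min(clean.time_ms.size, int(nxt - t0))
        if b > a:
            d = np.hypot(clean.x_deg[a:b] - seg.x_deg, clean.y_deg[a:b] - seg.y_deg)
            near = (d < FIXATION_RADIUS_DEG) & ~clean.mask[a:b]
            hold = int(FIXATION_HOLD_MS)
            if near.size >= hold:
                ok = np.convolve(near.astype(np.int32), np.ones(hold, dtype=np.int32),
                                 mode="valid") == hold
                hit = np.nonzero(ok)[0]
                if hit.size:
                    row["time_to_fixate_ms"] = float(hit[0])
        rows.append(row)
    return pd.DataFrame(rows)


def compute_pursuit_metrics(clean: CleanTrace, schedule: TaskSchedule,
                            detection: DetectionResult) -> pd.DataFrame:
    """Per-cycle pursuit gain and catch-up saccade counts.

    Gain is the median, over pursuit-on samples of the cycle (excluding
    saccade intervals, masked samples and the first 100 ms), of eye speed
    divided by the constant target speed.
    """
    if schedule.task != "pursuit":
        raise ValueError("expected a pursuit schedule")
    target_speed = schedule.pursuit_target_speed_deg_s
    n = clean.time_ms.size
    t0 = float(clean.time_ms[0]) if n else 0.0
    in_saccade = np.zeros(n, dtype=bool)
    for ev in detection.saccades:
        a = max(0, int(ev.onset_ms - t0) - 10)
        b = min(n, int(ev.offset_ms - t0) + 10)
        in_saccade[a:b] = True
    rows = []
    cycle = 0
    first_on = next((s.onset_ms for s in schedule.segments if s.kind == "pursuit_on"),
                    0.0)
    acquisition_end = first_on + 500.0  # initial foveation is not a catch-up
    for seg in schedule.segments:
        if seg.kind != "pursuit_on":
            continue
        cycle += 1
        a = int(seg.onset_ms - t0) + int(FIXATION_HOLD_MS)
        b = min(n, int(seg.offset_ms - t0))
        row = dict(cycle=cycle, pursuit_velocity_gain=np.nan,
                   catch_up_saccade_count=0, missing=True)
        if b > a:
            ok = ~clean.mask[a:b] & ~in_saccade[a:b]
            if ok.any():
                row["pursuit_velocity_gain"] = float(
                    np.median(clean.speed_deg_s[a:b][ok]) / target_speed)
                row["missing"] = False
        row["catch_up_saccade_count"] = int(sum(
            max(seg.onset_ms, acquisition_end) <= ev.onset_ms < seg.offset_ms
            for ev in detection.saccades))
        rows.append(row)
    return pd.DataFrame(rows)


def compute_antisaccade_metrics(clean: CleanTrace, schedule: TaskSchedule,
                                detection: DetectionResult) -> pd.DataFrame:
    """Per-cue anti-saccade metrics plus premature fixation breaks.

    The first >=1 deg saccade after cue onset is the response; it is an error
    when its horizontal direction points toward the cue.  Premature saccades
    are those leaving a 2 deg central window during a central fixation.
    Reaction time is recorded for correct anti-saccades only.
    """
    if schedule.task != "antisaccade":
        raise ValueError("expected an anti-saccade schedule")
    sac = detection.saccades
    onsets = np.array([s.onset_ms for s in sac])
    amps = np.array([s.amplitude_deg for s in sac])
    rows = []
    cue_index = -1
    for k, seg in enumerate(schedule.segments):
        if seg.kind != "peripheral_cue":
            continue
        cue_index += 1
        side = float(np.sign(seg.x_deg))
        win_end = seg.offset_ms + 400.0
        row = dict(cue=cue_index, antisaccade_error=np.nan,
                   reaction_time_ms=np.nan, premature_count=0, missing=True)
        sel = np.nonzero((onsets >= seg.onset_ms + ANTICIPATION_CUTOFF_MS)
                         & (onsets < win_end) & (amps >= MIN_RESPONSE_AMP_DEG))[0]
        if sel.size:
            ev = sac[sel[0]]
            err = float(np.sign(ev.x1 - ev.x0)) == side
            row["antisaccade_error"] = bool(err)
            row["missing"] = False
            if not err:
                row["reaction_time_ms"] = ev.onset_ms - seg.onset_ms
        rows.append(row)
    # premature saccades per central fixation
    pre_rows = []
    for k, seg in enumerate(schedule.segments):
        if seg.kind != "central_fixation":
            continue
        cnt = 0
        for ev in sac:
            if seg.onset_ms <= ev.onset_ms < seg.offset_ms:
                if math.hypot(ev.x0, ev.y0) < FIXATION_RADIUS_DEG <= math.hypot(ev.x1, ev.y1):
                    cnt += 1
        pre_rows.append(cnt)
    df = pd.DataFrame(rows)
    df.attrs["premature_per_fixation"] = pre_rows
    return df


def _med_sd(values) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan"), float("nan")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(np.median(v)), sd


def _count_channels(counts) -> tuple[float, float]:
    v = np.asarray(counts, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan"), float("nan")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(np.sum(v)), sd


def aggregate_feature_vector(vgs_metrics: pd.DataFrame | None,
                             pursuit_metrics: pd.DataFrame | None,
                             anti_metrics: pd.DataFrame | None,
                             vgs_detection: DetectionResult | None = None,
                             pursuit_detection: DetectionResult | None = None,
                             anti_detection: DetectionResult | None = None,
                             ) -> pd.Series:
    """Collapse trial-level metrics into the fixed-order feature vector."""
    out = {name: float("nan") for name in FEATURE_NAMES}
    if vgs_metrics is not None and len(vgs_metrics):
        m = vgs_metrics
        for base, col in (("reaction_time", "reaction_time_ms"),
                          ("landing_error", "landing_error_deg"),
                          ("time_to_fixate", "time_to_fixate_ms"),
                          ("q_ratio", "q_ratio"),
                          ("peak_mean_ratio", "peak_mean_ratio")):
            out[f"vgs_{base}_med"], out[f"vgs_{base}_sd"] = _med_sd(m[col])
        out["vgs_premature_total"], out["vgs_premature_sd"] = _count_channels(m["premature_count"])
    if pursuit_metrics is not None and len(pursuit_metrics):
        m = pursuit_metrics
        out["sp_gain_med"], out["sp_gain_sd"] = _med_sd(m["pursuit_velocity_gain"])
        out["sp_catchup_total"], out["sp_catchup_sd"] = _count_channels(
            m["catch_up_saccade_count"])
    if anti_metrics is not None and len(anti_metrics):
        m = anti_metrics
        errs = m["antisaccade_error"].astype(float)
        out["as_error_total"], out["as_error_sd"] = _count_channels(errs)
        out["as_reaction_time_med"], out["as_reaction_time_sd"] = _med_sd(m["reaction_time_ms"])
        pre = m.attrs.get("premature_per_fixation", [])
        if pre:
            out["as_premature_total"], out["as_premature_sd"] = _count_channels(pre)
    for task, det in (("vgs", vgs_detection), ("sp", pursuit_detection),
                      ("as", anti_detection)):
        if det is not None:
            out[f"{task}_main_sequence_slope"] = main_sequence_slope(det.saccades)
            if task != "sp" and det.fixations:
                disp = [f.dispersion_deg for f in det.fixations]
                out[f"{task}_fixation_dispersion_med"], out[f"{task}_fixation_dispersion_sd"] = \
                    _med_sd(disp)
    return pd.Series(out, index=FEATURE_NAMES, dtype=float)


def extract_session_features(traces: dict, schedules: dict) -> pd.Series:
    """Run preprocessing, detection and aggregation for one session.

    ``traces`` and ``schedules`` map task names ('visually_guided',
    'pursuit', 'antisaccade') to a :class:`GazeTrace` and its schedule;
    any task may be absent (its features come back NaN).
    """
    from .gaze_events import detect_saccades, preprocess

    metrics = {"vgs": None, "sp": None, "as": None}
    detections = {"vgs": None, "sp": None, "as": None}
    if "visually_guided" in traces:
        clean = preprocess(traces["visually_guided"])
        det = detect_saccades(clean)
        metrics["vgs"] = compute_saccade_task_metrics(clean, schedules["visually_guided"], det)
        detections["vgs"] = det
    if "pursuit" in traces:
        clean = preprocess(traces["pursuit"])
        det = detect_saccades(clean)
        metrics["sp"] = compute_pursuit_metrics(clean, schedules["pursuit"], det)
        detections["sp"] = det
    if "antisaccade" in traces:
        clean = preprocess(traces["antisaccade"])
        det = detect_saccades(clean)
        metrics["as"] = compute_antisaccade_metrics(clean, schedules["antisaccade"], det)
        detections["as"] = det
    return aggregate_feature_vector(metrics["vgs"], metrics["sp"], metrics["as"],
                                    detections["vgs"], detections["sp"], detections["as"])
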