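"""Gaze-trace preprocessing and saccade/fixation segmentation.

Detection is a fixed-threshold velocity algorithm, adequate for 1 kHz
video-oculography with low noise: positions are low-pass filtered with a
centred moving average, speed is the Euclidean norm of the centred-difference
derivative, and saccades are maximal spans with speed above 30 deg/s lasting
at least 4 ms.  Spans separated by less than 20 ms are merged; events smaller
than 0.5 deg or touching a blink mask are discarded.  All constants are
keyword arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, uniform_filter1d

from .synthetic_cohort import GazeTrace


@dataclass(frozen=True)
class SaccadeEvent:
    """A detected saccade with kinematic attributes from the filtered trace."""

    onset_ms: float
    offset_ms: float
    amplitude_deg: float
    peak_velocity_deg_s: float
    mean_velocity_deg_s: float
    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    @property
    def q_ratio(self) -> float:
        """Peak velocity x duration / amplitude; 1 for a rectangular velocity
        profile, 2 for a triangular one, and never below 1 because the net
        displacement cannot exceed peak speed times duration."""
        return self.peak_velocity_deg_s * (self.duration_ms / 1000.0) / self.amplitude_deg

    @property
    def peak_mean_ratio(self) -> float:
        return self.peak_velocity_deg_s / self.mean_velocity_deg_s


@dataclass(frozen=True)
class FixationEvent:
    onset_ms: float
    offset_ms: float
    x_deg: float
    y_deg: float
    dispersion_deg: float  # RMS distance of samples from the centroid

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class CleanTrace:
    """Filtered positions with a velocity series and a blink/invalid mask."""

    task: str
    time_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    speed_deg_s: np.ndarray  # NaN on masked samples
    mask: np.ndarray  # True where the sample carries no information
    subject_id: str = "s0"
    session: int = 1


@dataclass
class DetectionResult:
    saccades: list
    fixations: list  # inter-saccade spans (pursuit task: empty, see epochs)
    pursuit_epochs: list  # FixationEvent-shaped spans for the pursuit task


def preprocess(trace: GazeTrace, blink_pad_ms: float = 50.0,
               smooth_window_ms: float = 20.0) -> CleanTrace:
    """Mask blinks (padded), low-pass filter positions, differentiate.

    Invalid samples and their ±``blink_pad_ms`` neighbourhoods are masked and
    carry no velocity; positions are interpolated across masked spans before
    filtering so the filter does not smear NaNs into valid data.
    """
    n = trace.n
    window = max(1, int(round(smooth_window_ms)) | 1)  # odd number of samples
    if n < window or n < 3:
        raise ValueError("trace shorter than the smoothing window")
    dt_s = 1e-3 * np.median(np.diff(trace.time_ms)) if n > 1 else 1e-3
    invalid = ~trace.valid.astype(bool)
    invalid |= ~np.isfinite(trace.x_deg) | ~np.isfinite(trace.y_deg)
    pad = int(round(blink_pad_ms))
    mask = binary_dilation(invalid, np.ones(2 * pad + 1, dtype=bool)) if pad else invalid
    x = trace.x_deg.astype(float).copy()
    y = trace.y_deg.astype(float).copy()
    if invalid.any():
        good = ~invalid
        if not good.any():
            raise ValueError("trace has no valid samples")
        idx = np.arange(n)
        x = np.interp(idx, idx[good], x[good])
        y = np.interp(idx, idx[good], y[good])
    if window > 1:
        x = uniform_filter1d(x, size=window, mode="nearest")
        y = uniform_filter1d(y, size=window, mode="nearest")
    vx = np.gradient(x, dt_s)
    vy = np.gradient(y, dt_s)
    speed = np.hypot(vx, vy)
    speed[mask] = np.nan
    return CleanTrace(trace.task, trace.time_ms, x, y, speed, mask,
                      trace.subject_id, trace.session)


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where ``flags`` is True."""
    d = np.diff(flags.astype(np.int8), prepend=0, append=0)
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    return list(zip(starts, stops))


def detect_saccades(clean: CleanTrace, onset_thresh_deg_s: float = 30.0,
                    min_duration_ms: float = 4.0, min_amplitude_deg: float = 0.5,
                    merge_gap_ms: float = 20.0, min_fixation_ms: float = 40.0,
                    ) -> DetectionResult:
    """Velocity-threshold segmentation into saccades and fixations.

    Inter-saccade spans of at least ``min_fixation_ms`` become fixations,
    except for the pursuit task where they are labelled pursuit epochs.
    Events overlapping the blink mask are dropped rather than truncated so
    their kinematics are never computed from corrupt samples.
    """
    n = clean.time_ms.size
    if n == 0:
        return DetectionResult([], [], [])
    with np.errstate(invalid="ignore"):
        above = clean.speed_deg_s > onset_thresh_deg_s
    above &= ~clean.mask
    spans = _runs(above)
    # merge spans separated by a short gap
    merged: list[list[int]] = []
    for a, b in spans:
        if merged and a - merged[-1][1] < merge_gap_ms:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    saccades: list[SaccadeEvent] = []
    for a, b in merged:
        if b - a < min_duration_ms:
            continue
        if clean.mask[a:b].any():
            continue
        # amplitude between positions at onset and offset, duration
        # offset-onset: consistent definitions keep Q-ratio >= 1
        i0 = a
        i1 = min(n - 1, b)
        amp = float(np.hypot(clean.x_deg[i1] - clean.x_deg[i0],
                             clean.y_deg[i1] - clean.y_deg[i0]))
        if amp < min_amplitude_deg:
            continue
        seg_speed = clean.speed_deg_s[a:b]
        saccades.append(SaccadeEvent(
            onset_ms=float(clean.time_ms[i0]),
            offset_ms=float(clean.time_ms[i0] + (i1 - i0)),
            amplitude_deg=amp,
            peak_velocity_deg_s=float(np.max(seg_speed)),
            mean_velocity_deg_s=float(np.mean(seg_speed)),
            x0=float(clean.x_deg[i0]), y0=float(clean.y_deg[i0]),
            x1=float(clean.x_deg[i1]), y1=float(clean.y_deg[i1]),
        ))
    # complement spans: fixations (or pursuit epochs)
    in_saccade = np.zeros(n, dtype=bool)
    t0 = float(clean.time_ms[0])
    for ev in saccades:
        in_saccade[int(ev.onset_ms - t0):int(ev.offset_ms - t0)] = True
    quiet = ~in_saccade & ~clean.mask
    fixations: list[FixationEvent] = []
    for a, b in _runs(quiet):
        if b - a < min_fixation_ms:
            continue
        xs = clean.x_deg[a:b]
        ys = clean.y_deg[a:b]
        cx, cy = float(np.mean(xs)), float(np.mean(ys))
        disp = float(np.sqrt(np.mean((xs - cx) ** 2 + (ys - cy) ** 2)))
        fixations.append(FixationEvent(float(clean.time_ms[a]),
                                       float(clean.time_ms[b - 1] + 1.0),
                                       cx, cy, disp))
    if clean.task == "pursuit":
        return DetectionResult(saccades, [], fixations)
    return DetectionResult(saccades, fixations, [])


def match_events(detected, truth_onsets_ms, tol_ms: float = 25.0):
    """Greedy one-to-one matching of detected saccades to ground-truth onsets.

    Returns ``(pairs, recall, precision)`` where ``pairs`` is a list of
    ``(truth_index, detected_index, onset_error_ms)``.  Used to score the
    detector against the simulator's injected-event log.
    """
    truth = np.asarray(truth_onsets_ms, dtype=float)
    det = np.asarray([ev.onset_ms for ev in detected], dtype=float)
    used = np.zeros(det.size, dtype=bool)
    pairs = []
    for ti in np.argsort(truth):
        if det.size == 0:
            break
        err = np.abs(det - truth[ti])
        err[used] = np.inf
        di = int(np.argmin(err))
        if err[di] <= tol_ms:
            used[di] = True
            pairs.append((int(ti), di, float(det[di] - truth[ti])))
    recall = len(pairs) / truth.size if truth.size else 1.0
    precision = len(pairs) / det.size if det.size else 1.0
    return pairs, recall, precision


def events_to_frame(result: DetectionResult):
    """Flatten a detection result to the event-table CSV schema."""
    import pandas as pd

    rows = []
    for ev in result.saccades:
        rows.append(dict(kind="saccade", onset_ms=ev.onset_ms, offset_ms=ev.offset_ms,
                         amplitude_deg=ev.amplitude_deg, duration_ms=ev.duration_ms,
                         peak_vel=ev.peak_velocity_deg_s, mean_vel=ev.mean_velocity_deg_s,
                         x0=ev.x0, y0=ev.y0, x1=ev.x1, y1=ev.y1, dispersion_deg=np.nan))
    for kind, evs in (("fixation", result.fixations), ("pursuit_epoch", result.pursuit_epochs)):
        for fx in evs:
            rows.append(dict(kind=kind, onset_ms=fx.onset_ms, offset_ms=fx.offset_ms,
                             amplitude_deg=np.nan, duration_ms=fx.duration_ms,
                             peak_vel=np.nan, mean_vel=np.nan, x0=fx.x_deg, y0=fx.y_deg,
                             x1=fx.x_deg, y1=fx.y_deg, dispersion_deg=fx.dispersion_deg))
    cols = ["kind", "onset_ms", "offset_ms", "amplitude_deg", "duration_ms",
            "peak_vel", "mean_vel", "x0", "y0", "x1", "y1", "dispersion_deg"]
    return pd.DataFrame(rows, columns=cols).sort_values("onset_ms", ignore_index=True)
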