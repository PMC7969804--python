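"""Oculomotor feature battery: per-trial metrics and session aggregation."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from oculoseason.gaze_events import SaccadeEvent, detect_saccades, preprocess
from oculoseason.oculo_features import (
    FEATURE_CHANNEL,
    FEATURE_NAMES,
    aggregate_feature_vector,
    compute_antisaccade_metrics,
    compute_pursuit_metrics,
    compute_saccade_task_metrics,
    extract_session_features,
)
from oculoseason.stimulus import (
    make_antisaccade_schedule,
    make_pursuit_schedule,
    make_visually_guided_schedule,
)
from oculoseason.synthetic_cohort import GazeTrace, SubjectParams, simulate_trace


def _pipeline(schedule, params, seed):
    trace, log = simulate_trace(schedule, params, seed=seed)
    clean = preprocess(trace)
    return clean, log, detect_saccades(clean)


class TestQRatio:
    def test_rectangular_profile_formula(self):
        # amplitude = peak x duration  ->  Q = 1
        ev = SaccadeEvent(0, 40, amplitude_deg=4.0, peak_velocity_deg_s=100.0,
                          mean_velocity_deg_s=100.0, x0=0, y0=0, x1=4, y1=0)
        assert ev.q_ratio == pytest.approx(1.0)

    def test_triangular_profile_formula(self):
        # amplitude = peak x duration / 2  ->  Q = 2
        ev = SaccadeEvent(0, 40, amplitude_deg=2.0, peak_velocity_deg_s=100.0,
                          mean_velocity_deg_s=50.0, x0=0, y0=0, x1=2, y1=0)
        assert ev.q_ratio == pytest.approx(2.0)

    @pytest.mark.parametrize("profile,expected,tol", [("rect", 1.0, 0.1),
                                                      ("tri", 2.0, 0.15)])
    def test_synthetic_velocity_profiles_on_trace(self, profile, expected, tol):
        """Detector-level Q on traces built from ideal velocity profiles."""
        n, d, v = 2000, 60, 200.0  # 60 ms saccade, 200 deg/s peak
        t = np.arange(d, dtype=float)
        if profile == "rect":
            vel = np.full(d, v)
        else:
            vel = v * (1.0 - np.abs(2 * t / (d - 1) - 1.0))
        x = np.zeros(n)
        x[1000:1000 + d] = np.cumsum(vel) / 1000.0
        x[1000 + d:] = x[1000 + d - 1]
        trace = GazeTrace("visually_guided", np.arange(n, dtype=float), x,
                          np.zeros(n), np.ones(n, dtype=bool))
        clean = preprocess(trace, smooth_window_ms=0)
        # low threshold so the triangle's slow tails are inside the event
        res = detect_saccades(clean, onset_thresh_deg_s=5.0)
        assert len(res.saccades) == 1
        assert res.saccades[0].q_ratio == pytest.approx(expected, abs=tol)


class TestSaccadeTaskMetrics:
    def test_ideal_responder_reaction_time_and_accuracy(self, vgs_schedule,
                                                        noise_free_params):
        clean, log, det = _pipeline(vgs_schedule, noise_free_params, seed=13)
        m = compute_saccade_task_metrics(clean, vgs_schedule, det)
        assert np.nanmedian(m["reaction_time_ms"]) == pytest.approx(200.0, abs=5.0)
        assert np.nanmedian(m["landing_error_deg"]) < 0.1
        assert m["missing"].mean() < 0.05

    def test_premature_counts_match_injected(self, vgs_schedule):
        p = SubjectParams(premature_rate=0.3, gaze_noise_deg=0.0)
        clean, log, det = _pipeline(vgs_schedule, p, seed=17)
        m = compute_saccade_task_metrics(clean, vgs_schedule, det)
        injected = (log["kind"] == "premature").sum()
        assert m["premature_count"].sum() == injected

    def test_no_response_marked_missing(self, noise_free_params):
        sched = make_visually_guided_schedule(positions_deg=[-5.0, 5.0], n_jumps=2,
                                              seed=0)
        # latency beyond the dwell: subject never responds in time
        p = replace(noise_free_params, latency_mean_ms=5000.0)
        clean, _, det = _pipeline(sched, p, seed=3)
        m = compute_saccade_task_metrics(clean, sched, det)
        assert m["missing"].all()
        assert m["reaction_time_ms"].isna().all()

    def test_main_sequence_slope_recovered(self, vgs_schedule, noise_free_params):
        clean, _, det = _pipeline(vgs_schedule, noise_free_params, seed=19)
        from oculoseason.oculo_features import main_sequence_slope

        slope = main_sequence_slope(det.saccades)
        assert slope == pytest.approx(2.5, rel=0.10)


class TestPursuitMetrics:
    def test_perfect_tracking_gain_one_no_catchups(self, pursuit_schedule,
                                                   noise_free_params):
        p = replace(noise_free_params, pursuit_gain=1.0)
        clean, _, det = _pipeline(pursuit_schedule, p, seed=2)
        m = compute_pursuit_metrics(clean, pursuit_schedule, det)
        assert np.nanmedian(m["pursuit_velocity_gain"]) == pytest.approx(1.0, abs=0.02)
        assert m["catch_up_saccade_count"].sum() == 0

    def test_stationary_eye_gain_zero(self, pursuit_schedule):
        n = pursuit_schedule.n_samples
        trace = GazeTrace("pursuit", np.arange(n, dtype=float), np.zeros(n),
                          np.zeros(n), np.ones(n, dtype=bool))
        clean = preprocess(trace)
        m = compute_pursuit_metrics(clean, pursuit_schedule, detect_saccades(clean))
        assert np.nanmedian(m["pursuit_velocity_gain"]) == pytest.approx(0.0, abs=1e-6)

    def test_programmed_gain_and_catchups_recovered(self, pursuit_schedule):
        p = SubjectParams(pursuit_gain=0.8)
        clean, log, det = _pipeline(pursuit_schedule, p, seed=5)
        m = compute_pursuit_metrics(clean, pursuit_schedule, det)
        assert np.nanmedian(m["pursuit_velocity_gain"]) == pytest.approx(0.8, abs=0.05)
        first_on = next(s.onset_ms for s in pursuit_schedule.segments
                        if s.kind == "pursuit_on")
        injected = ((log["kind"] == "catchup")
                    & (log["onset_ms"] >= first_on + 500.0)).sum()
        assert m["catch_up_saccade_count"].sum() == injected


class TestAntisaccadeMetrics:
    @pytest.mark.parametrize("error_p,expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_degenerate_error_rates(self, anti_schedule, error_p, expected):
        p = SubjectParams(antisaccade_error_p=error_p)
        clean, _, det = _pipeline(anti_schedule, p, seed=23)
        m = compute_antisaccade_metrics(clean, anti_schedule, det)
        assert m["antisaccade_error"].astype(float).mean() == pytest.approx(expected)

    def test_flags_match_injected_error_log(self):
        sched = make_antisaccade_schedule(seed=9)
        p = SubjectParams(antisaccade_error_p=0.3)
        clean, log, det = _pipeline(sched, p, seed=9)
        m = compute_antisaccade_metrics(clean, sched, det)
        injected = (log[log["kind"] == "response"].sort_values("cue_index")
                    .set_index("cue_index")["is_error"].astype(bool))
        got = m.set_index("cue")["antisaccade_error"]
        assert not got.isna().any()
        assert (got.loc[injected.index].astype(bool) == injected).all()

    def test_reaction_time_only_for_correct_trials(self, anti_schedule):
        p = SubjectParams(antisaccade_error_p=1.0)
        clean, _, det = _pipeline(anti_schedule, p, seed=25)
        m = compute_antisaccade_metrics(clean, anti_schedule, det)
        assert m["reaction_time_ms"].isna().all()


class TestAggregation:
    def test_median_of_printed_values(self):
        m = pd.DataFrame(dict(step=[1, 2, 3], reaction_time_ms=[180.0, 200.0, 240.0],
                              landing_error_deg=1.0, time_to_fixate_ms=250.0,
                              q_ratio=1.6, peak_mean_ratio=1.6, premature_count=0,
                              missing=False))
        vec = aggregate_feature_vector(m, None, None)
        assert vec["vgs_reaction_time_med"] == 200.0

    def test_constant_metric_zero_dispersion(self):
        m = pd.DataFrame(dict(step=[1, 2, 3], reaction_time_ms=200.0,
                              landing_error_deg=1.0, time_to_fixate_ms=250.0,
                              q_ratio=1.6, peak_mean_ratio=1.6, premature_count=1,
                              missing=False))
        vec = aggregate_feature_vector(m, None, None)
        assert vec["vgs_reaction_time_sd"] == 0.0
        assert vec["vgs_premature_total"] == 3.0
        assert vec["vgs_premature_sd"] == 0.0

    def test_all_missing_metric_flagged_nan(self):
        vec = aggregate_feature_vector(None, None, None)
        assert vec.isna().all()
        assert list(vec.index) == FEATURE_NAMES

    def test_registry_bookkeeping(self):
        assert len(FEATURE_NAMES) == 29
        assert len(set(FEATURE_NAMES)) == 29
        assert set(FEATURE_CHANNEL.values()) == {"central", "dispersion"}
        n_disp = sum(1 for v in FEATURE_CHANNEL.values() if v == "dispersion")
        assert n_disp == 13

    def test_full_session_vector_deterministic_and_complete(self, noise_free_params):
        schedules = {
            "visually_guided": make_visually_guided_schedule(n_jumps=10, seed=3),
            "pursuit": make_pursuit_schedule(n_cycles=4),
            "antisaccade": make_antisaccade_schedule(n_peripheral=4, seed=3),
        }
        p = SubjectParams()
        traces = {k: simulate_trace(s, p, seed=50 + i)[0]
                  for i, (k, s) in enumerate(schedules.items())}
        v1 = extract_session_features(traces, schedules)
        v2 = extract_session_features(traces, schedules)
        pd.testing.assert_series_equal(v1, v2)
        assert list(v1.index) == FEATURE_NAMES
        assert v1.notna().sum() > 20
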