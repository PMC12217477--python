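"""Tracking QC, calibration, speed, bout detection, responses, annotations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import photomotor as pm
from photomotor.behavior import (
    BoutSet,
    EventTable,
    TrackingTable,
    classify_stimulus_responses,
    compute_calibration,
    compute_speed,
    detect_bouts,
    load_annotations,
    qc_filter_positions,
)
from conftest import brute_force_bouts, make_speed_trace

SQUARE_400 = np.array([[0, 0], [400, 0], [400, 400], [0, 400]], float)


def make_tracking(x, y, likelihood=None, fps=20.0, corners=SQUARE_400):
    x = np.asarray(x, float)
    if likelihood is None:
        likelihood = np.full(x.size, 0.99)
    return TrackingTable(
        time=np.arange(x.size) / fps,
        x=x,
        y=np.asarray(y, float),
        likelihood=np.asarray(likelihood, float),
        corners=corners,
        fps=fps,
    )


class TestCalibration:
    def test_square_400px_gives_point_one(self):
        assert compute_calibration(SQUARE_400, 40.0) == pytest.approx(0.1)

    def test_square_100px_gives_point_four(self):
        c = np.array([[0, 0], [100, 0], [100, 100], [0, 100]], float)
        assert compute_calibration(c, 40.0) == pytest.approx(0.4)

    def test_uneven_sides_average_to_scale(self):
        # quadrilateral with sides 400, 400, 392, 408 px (mean 400)
        x = (416 - np.sqrt(416**2 - 4 * 3296)) / 2
        d = np.array([x, 416 - x])
        corners = np.array([[0, 0], [400, 0], [400, 400], d], float)
        sides = np.linalg.norm(np.roll(corners, -1, axis=0) - corners, axis=1)
        np.testing.assert_allclose(sorted(sides), [392, 400, 400, 408], atol=1e-9)
        assert compute_calibration(corners, 40.0) == pytest.approx(0.1)

    def test_degenerate_quadrilateral_rejected(self):
        c = np.array([[0, 0], [400, 0], [200, 0], [100, 0]], float)
        with pytest.raises(ValueError):
            compute_calibration(c, 40.0)


class TestQC:
    def test_likelihood_threshold_is_strict(self):
        tr = make_tracking([200, 200, 200], [200, 200, 200], [0.79, 0.80, 0.99])
        qc = qc_filter_positions(tr, scale=0.1)
        assert list(qc.valid) == [False, True, True]
        assert qc.counts["likelihood"] == 1

    def test_positions_outside_arena_excluded(self):
        tr = make_tracking([200, 500, 200], [200, 200, 200])
        qc = qc_filter_positions(tr, scale=0.1)
        assert list(qc.valid) == [True, False, True]
        assert qc.counts["arena"] == 1

    def test_boundary_position_retained(self):
        tr = make_tracking([0.0, 5.0], [0.0, 5.0])
        qc = qc_filter_positions(tr, scale=0.1)
        assert qc.valid.all()

    def test_impossible_step_speed_excluded(self):
        # 400 px = 40 cm in 0.05 s -> 800 cm/s
        tr = make_tracking([0, 200, 200], [200, 200, 200])
        qc = qc_filter_positions(tr, scale=0.1)
        assert list(qc.valid) == [True, False, True]
        assert qc.counts["speed"] == 1

    def test_counts_conserve_total_frames(self, rng):
        n = 300
        x = rng.uniform(-50, 450, n)
        y = rng.uniform(-50, 450, n)
        lk = rng.uniform(0.5, 1.0, n)
        tr = make_tracking(x, y, lk)
        qc = qc_filter_positions(tr, scale=0.1)
        assert qc.n_retained + sum(qc.counts.values()) == n


class TestSpeed:
    def test_half_centimeter_in_fifty_ms_is_ten_cms(self):
        tr = make_tracking([200.0, 205.0], [200.0, 200.0])  # 5 px = 0.5 cm
        sp = compute_speed(tr, np.ones(2, bool), scale=0.1)
        assert sp.speed[1] == pytest.approx(10.0)

    def test_stationary_is_zero(self):
        tr = make_tracking([200.0] * 5, [200.0] * 5)
        sp = compute_speed(tr, np.ones(5, bool), scale=0.1)
        np.testing.assert_allclose(sp.speed[1:], 0.0)
        assert np.isnan(sp.speed[0])

    def test_gap_leaves_following_frame_missing(self):
        tr = make_tracking([200.0, 205.0, 210.0], [200.0] * 3)
        sp = compute_speed(tr, np.array([True, False, True]), scale=0.1)
        assert np.isnan(sp.speed[1]) and np.isnan(sp.speed[2])


class TestBoutDetection:
    def test_ten_frames_make_exactly_half_second(self):
        sp = make_speed_trace([0] * 5 + [5.0] * 10 + [0] * 5)
        bouts = detect_bouts(sp)
        assert len(bouts) == 1
        assert bouts.durations[0] == pytest.approx(0.5)

    def test_nine_frames_fall_short(self):
        sp = make_speed_trace([0] * 5 + [5.0] * 9 + [0] * 5)
        assert len(detect_bouts(sp)) == 0

    def test_threshold_is_strict_inequality(self):
        sp = make_speed_trace([3.0] * 40)
        assert len(detect_bouts(sp)) == 0
        sp = make_speed_trace([3.0 + 1e-9] * 40)
        assert len(detect_bouts(sp)) == 1

    def test_missing_frame_terminates_run(self):
        v = [5.0] * 8 + [np.nan] + [5.0] * 8
        assert len(detect_bouts(make_speed_trace(v))) == 0

    def test_matches_brute_force_oracle_on_random_traces(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 120))
            v = rng.exponential(3.0, n)
            v[rng.random(n) < 0.1] = np.nan
            det = detect_bouts(make_speed_trace(v))
            got = list(map(tuple, det.table[["onset_s", "offset_s"]].to_numpy()))
            expected = brute_force_bouts(v)
            np.testing.assert_allclose(got, expected)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 12.0), min_size=1, max_size=60),
        st.floats(0.5, 6.0),
        st.floats(0.1, 1.2),
    )
    def test_raising_thresholds_never_adds_bouts(self, v, thr, mindur):
        sp = make_speed_trace(v)
        base = len(detect_bouts(sp, threshold=thr, min_duration=mindur))
        assert len(detect_bouts(sp, threshold=thr + 1.0, min_duration=mindur)) <= base
        assert len(detect_bouts(sp, threshold=thr, min_duration=mindur + 0.2)) <= base


class TestResponses:
    def _events(self, onsets):
        return EventTable(pd.DataFrame({"onset_s": onsets, "modality": "sound"}))

    def test_bout_onset_inside_window_is_responsive(self):
        v = np.zeros(400)
        v[240:260] = 10.0  # bout onset at 12 s, stimulus at 10 s
        flags, prop = classify_stimulus_responses(self._events([10.0]), make_speed_trace(v))
        assert flags["response"].tolist() == [True]
        assert prop == 1.0

    def test_bout_after_window_is_not_responsive(self):
        v = np.zeros(500)
        v[320:340] = 10.0  # onset at 16 s, stimulus at 10 s
        flags, _ = classify_stimulus_responses(self._events([10.0]), make_speed_trace(v))
        assert flags["response"].tolist() == [False]

    def test_proportion_of_responsive_trials(self):
        v = np.zeros(20 * 20 * 9)
        # bouts shortly after trials 1 and 2 only
        for t0 in (10.0, 30.0):
            i = int((t0 + 2.0) * 20)
            v[i : i + 20] = 8.0
        onsets = [10.0 + 20.0 * k for k in range(8)]
        flags, prop = classify_stimulus_responses(self._events(onsets), make_speed_trace(v))
        assert prop == pytest.approx(0.25)

    def test_trial_past_recording_end_dropped(self):
        v = np.zeros(100)  # 5 s of recording
        with pytest.warns(UserWarning, match="dropped"):
            flags, _ = classify_stimulus_responses(self._events([3.0]), make_speed_trace(v))
        assert len(flags) == 0


class TestAnnotations:
    def test_valid_rows_load(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("onset_s,offset_s,behavior\n10.0,16.8,grooming\n20.0,24.0,rearing\n")
        bouts = load_annotations(p)
        assert len(bouts) == 2
        g = bouts.of_kind("grooming")
        assert g["offset_s"][0] - g["onset_s"][0] == pytest.approx(6.8)

    def test_reversed_interval_reports_line(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("onset_s,offset_s,behavior\n5.0,4.0,rearing\n")
        with pytest.raises(ValueError, match="line 2"):
            load_annotations(p)

    def test_unknown_behavior_rejected(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("onset_s,offset_s,behavior\n1.0,2.0,sleeping\n")
        with pytest.raises(ValueError, match="sleeping"):
            load_annotations(p)

    def test_empty_file_gives_empty_set(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("onset_s,offset_s,behavior\n")
        assert len(load_annotations(p)) == 0

    def test_overlapping_same_kind_rejected(self):
        df = pd.DataFrame(
            {
                "onset_s": [1.0, 2.0],
                "offset_s": [3.0, 4.0],
                "kind": ["grooming", "grooming"],
                "source": ["manual", "manual"],
            }
        )
        with pytest.raises(ValueError, match="overlap"):
            BoutSet(df)


class TestTrackingRoundTrip:
    def test_dlc_csv_round_trip(self, tmp_path):
        tracking, _ = pm.synthgen.synthesize_tracking(
            [(2.0, 1.0, 10.0)], duration=10.0, seed=0
        )
        p = tmp_path / "track.csv"
        tracking.to_dlc_csv(p)
        back = TrackingTable.from_dlc_csv(p, fps=20.0)
        np.testing.assert_allclose(back.x, tracking.x)
        np.testing.assert_allclose(back.y, tracking.y)
        np.testing.assert_allclose(back.corners, tracking.corners)
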