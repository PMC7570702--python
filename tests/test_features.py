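import numpy as np
import pytest

import turnkit as tk
from turnkit.features import AXES, PHASES, feature_manifest

from conftest import FS, make_recording, make_trace


def _minjerk_trace(angle, dur, start=2.0, total=8.0, location="L5"):
    t = np.arange(int(total * FS)) / FS
    tau = np.clip((t - start) / dur, 0, 1)
    inside = (t > start) & (t < start + dur)
    omega = np.where(inside, (angle / dur) * (30 * tau**2 - 60 * tau**3 + 30 * tau**4), 0.0)
    return make_trace(omega, location=location)


class TestManifest:
    def test_total_and_per_location_counts(self):
        m = feature_manifest()
        counts = m.counts()
        assert len(m.entries) == 425
        for loc in ("HD", "C7", "L5"):
            assert counts[loc] == {"spatiotemporal": 21, "signal": 88}
        for role in ("inner", "outer"):
            assert counts[role] == {"spatiotemporal": 9, "signal": 40}

    def test_feature_ids_unique(self):
        ids = feature_manifest().feature_ids
        assert len(ids) == len(set(ids))

    def test_subset_filters_by_location_and_category(self):
        m = feature_manifest()
        assert len(m.subset(locations=["C7"], category="signal")) == 88
        assert len(m.subset(locations=["inner", "outer"])) == 98
        assert len(m.subset(category="spatiotemporal")) == 3 * 21 + 2 * 9


class TestSpatiotemporal:
    def test_single_turn_angular_velocity_closed_form(self):
        trace = _minjerk_trace(180.0, 2.0)
        turn = tk.TurnEvent("L5", 2.0, 4.0, 180.0)
        f = tk.extract_spatiotemporal([turn], None, "L5", trace)
        assert f["L5_angular_velocity_mean"] == pytest.approx(90.0)
        # theta/T expressed as angular frequency: 90 deg/s = 1.571 rad/s
        assert f["L5_angular_velocity_mean"] * np.pi / 180 == pytest.approx(1.571, abs=1e-3)
        assert f["L5_turn_time_mean"] == pytest.approx(2.0)
        assert f["L5_n_turns"] == 1

    def test_left_right_counts_follow_sign(self):
        trace = _minjerk_trace(175.0, 2.0)
        turns = [tk.TurnEvent("L5", 1.0, 3.0, -170.0),
                 tk.TurnEvent("L5", 4.0, 6.0, 175.0)]
        f = tk.extract_spatiotemporal(turns, None, "L5", trace)
        assert f["L5_n_left"] == 1 and f["L5_n_right"] == 1

    def test_identical_turns_have_zero_variability(self):
        trace = _minjerk_trace(180.0, 2.0)
        turn = tk.TurnEvent("L5", 2.0, 4.0, 180.0)
        f = tk.extract_spatiotemporal([turn, turn, turn], None, "L5", trace)
        for fid in ("L5_turn_time_sd", "L5_turn_angle_sd",
                    "L5_angular_velocity_sd", "L5_peak_angular_frequency_sd"):
            assert f[fid] == 0.0

    def test_peak_angular_frequency_is_max_rate_in_rad(self):
        trace = _minjerk_trace(180.0, 2.0)
        turn = tk.TurnEvent("L5", 2.0, 4.0, 180.0)
        f = tk.extract_spatiotemporal([turn], None, "L5", trace)
        # min-jerk peak rate = 1.875 * angle / T
        expected = np.deg2rad(1.875 * 180.0 / 2.0)
        assert f["L5_peak_angular_frequency_mean"] == pytest.approx(expected, rel=1e-3)

    def test_zero_turns_yield_all_nan(self):
        f = tk.extract_spatiotemporal([], None, "L5",
                                      _minjerk_trace(180, 2.0))
        assert len(f) == 21
        assert all(np.isnan(v) for v in f.values())

    def test_ankle_role_features_from_steps(self):
        turns = [tk.TurnEvent("L5", 1.0, 3.0, 180.0)]
        steps = [[tk.StepEvent("inner", 1.0, 1.5, 60.0),
                  tk.StepEvent("inner", 1.7, 2.2, 60.0),
                  tk.StepEvent("inner", 2.4, 2.9, 60.0)]]
        f = tk.extract_spatiotemporal(turns, steps, "inner")
        assert f["inner_steps_per_turn_mean"] == 3.0
        assert f["inner_step_angle_mean"] == pytest.approx(60.0)
        assert f["inner_step_angular_velocity_mean"] == pytest.approx(120.0)


class TestSignalOracles:
    def test_rms_of_sine_is_amplitude_over_sqrt2(self):
        A, f_hz = 0.3, 4.0
        n = int(8 * FS)
        t = np.arange(n) / FS
        acc = np.vstack([1.0 + A * np.sin(2 * np.pi * f_hz * t),
                         np.zeros(n), np.zeros(n)])
        rec = make_recording(acc=acc, n=n)
        turn = tk.TurnEvent("L5", 2.0, 5.0, 180.0)  # 12 whole periods
        out = tk.extract_signal(rec, [turn], "L5")
        assert out["L5_acc_rms_VT_overall"] == pytest.approx(A / np.sqrt(2), rel=5e-3)

    def test_jerk_of_linear_ramp_equals_slope(self):
        k = 0.8  # g/s
        n = int(8 * FS)
        t = np.arange(n) / FS
        acc = np.vstack([k * t, np.zeros(n), np.zeros(n)])
        rec = make_recording(acc=acc, n=n)
        turn = tk.TurnEvent("L5", 2.0, 5.0, 180.0)
        out = tk.extract_signal(rec, [turn], "L5")
        assert out["L5_jerk_rms_VT_overall"] == pytest.approx(k, rel=0.01)
        # near-zero range: only low-pass ripple remains on a pure ramp
        assert out["L5_jerk_range_VT_overall"] == pytest.approx(0.0, abs=0.05 * k)

    def test_constant_angular_velocity_has_zero_angular_acceleration(self):
        n = int(8 * FS)
        gyr = np.vstack([np.full(n, 50.0), np.zeros(n), np.zeros(n)])
        rec = make_recording(gyr=gyr, n=n)
        turn = tk.TurnEvent("L5", 2.0, 5.0, 150.0)
        out = tk.extract_signal(rec, [turn], "L5")
        assert out["L5_angacc_rms_VT_overall"] == pytest.approx(0.0, abs=1e-6)

    def test_gyro_rms_reported_in_rad_per_s(self):
        A, f_hz = 40.0, 4.0  # deg/s sine
        n = int(8 * FS)
        t = np.arange(n) / FS
        gyr = np.vstack([A * np.sin(2 * np.pi * f_hz * t),
                         np.zeros(n), np.zeros(n)])
        rec = make_recording(gyr=gyr, n=n)
        turn = tk.TurnEvent("L5", 2.0, 5.0, 150.0)
        out = tk.extract_signal(rec, [turn], "L5")
        expected = np.deg2rad(A) / np.sqrt(2)
        assert out["L5_gyr_rms_VT_overall"] == pytest.approx(expected, rel=5e-3)

    def test_too_short_turn_window_is_skipped(self):
        rec = make_recording(n=1280)
        turn = tk.TurnEvent("L5", 2.0, 2.01, 100.0)  # 1-2 samples
        with pytest.warns(UserWarning, match="skipped"):
            out = tk.extract_signal(rec, [turn], "L5")
        assert all(np.isnan(v) for v in out.values())


class TestInvariances:
    def _session_features(self, scale_acc=1.0, t_shift=0.0):
        n = int(10 * FS)
        t = np.arange(n) / FS + t_shift
        rng = np.random.default_rng(9)
        acc = scale_acc * (np.vstack([np.ones(n), np.zeros(n), np.zeros(n)])
                           + 0.1 * rng.standard_normal((3, n)))
        gyr = 0.5 * rng.standard_normal((3, n))
        rec = tk.ImuRecording("L5", t, acc, gyr, None, FS)
        turn = tk.TurnEvent("L5", 2.0 + t_shift, 5.0 + t_shift, 120.0)
        return tk.extract_signal(rec, [turn], "L5")

    def test_acc_scaling_scales_rms_and_jerk(self):
        base = self._session_features(1.0)
        scaled = self._session_features(3.0)
        for fid, v in base.items():
            if fid.split("_")[1] in ("acc", "jerk"):
                assert scaled[fid] == pytest.approx(3.0 * v, rel=1e-9), fid
            else:  # gyro-derived features untouched
                assert scaled[fid] == pytest.approx(v, rel=1e-9), fid

    def test_time_origin_invariance(self):
        a = self._session_features(t_shift=0.0)
        b = self._session_features(t_shift=100.0)
        for fid in a:
            assert a[fid] == pytest.approx(b[fid], rel=1e-9, abs=1e-12), fid


class TestFeatureMatrix:
    def test_matrix_shape_and_duplicate_rows(self, noiseless_session):
        session, _ = noiseless_session
        X, manifest = tk.build_feature_matrix([session, session])
        assert X.shape == (2, 425)
        assert list(X.columns) == manifest.feature_ids
        np.testing.assert_array_equal(X.iloc[0].to_numpy(), X.iloc[1].to_numpy())

    def test_zscore_standardization(self, noiseless_session, default_session):
        X, _ = tk.build_feature_matrix([noiseless_session[0], default_session[0]],
                                       standardize=True)
        col = X["L5_turn_time_mean"]
        assert abs(col.mean()) < 1e-9
        assert abs(col.std(ddof=1) - 1.0) < 1e-9

    def test_missing_ankles_give_nan_not_zero(self, noiseless_cfg):
        import dataclasses
        cfg = dataclasses.replace(noiseless_cfg, locations=("HD", "C7", "L5"))
        session, _ = tk.simulate_session(cfg)
        fv = tk.extract_session_features(session)
        assert np.isnan(fv.values["inner_steps_per_turn_mean"])
        assert np.isnan(fv.values["outer_jerk_rms_R_overall"])
        assert not np.isnan(fv.values["L5_turn_time_mean"])
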