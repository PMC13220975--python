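"""Feature-extraction tests: smoothing, wheel, eye, licks, spectra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import motistate as ms
from motistate import config as cfg
from motistate import features as feat
from motistate.synth import powerlaw_noise


def sliding_mean_oracle(x, window):
    """Brute-force centered moving mean with truncated edges."""
    x = np.asarray(x, dtype=float)
    left = (window - 1) // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo = max(i - left, 0)
        hi = min(i + (window - 1 - left) + 1, x.size)
        out[i] = x[lo:hi].mean()
    return out


class TestMovingMean:
    def test_window_one_identity(self):
        x = np.random.default_rng(0).normal(size=30)
        assert np.allclose(feat.moving_mean(x, 1), x)

    def test_constant_series(self):
        assert np.allclose(feat.moving_mean(np.full(40, 3.7), 50), 3.7)

    @pytest.mark.parametrize("window", [2, 3, 7, 50])
    def test_matches_oracle(self, window):
        x = np.arange(10, dtype=float)
        assert np.allclose(feat.moving_mean(x, window),
                           sliding_mean_oracle(x, window))

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=120),
           st.integers(1, 60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_oracle_property(self, values, window):
        got = feat.moving_mean(values, window)
        assert got.shape == (len(values),)
        assert np.allclose(got, sliding_mean_oracle(values, window),
                           rtol=1e-9, atol=1e-9)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            feat.moving_mean([1.0, 2.0], 0)


class TestWheelSpeed:
    def test_constant_voltage_zero_speed(self):
        assert np.allclose(feat.wheel_speed(np.full(100, 1.2), 100.0), 0.0)

    def test_double_wrap_per_second(self):
        """A ramp wrapping twice per second is 72 cm/s."""
        rate = 1000.0
        t = np.arange(0, 3, 1 / rate)
        v = np.mod(72.0 * t, 36.0) / 36.0 * 3.3
        speed = feat.wheel_speed(v, rate)
        assert np.allclose(speed[5:-5], 72.0, rtol=1e-6)

    def test_reversed_ramp_antisymmetric(self):
        rate = 200.0
        t = np.arange(0, 2, 1 / rate)
        v = np.mod(20.0 * t, 36.0) / 36.0 * 3.3
        fwd = feat.wheel_speed(v, rate)
        bwd = feat.wheel_speed(v[::-1], rate)
        assert np.allclose(bwd[1:], -fwd[::-1][1:], atol=1e-8)

    def test_speed_recovery_within_one_percent(self):
        rate = 100.0
        t = np.arange(0, 10, 1 / rate)
        v = np.mod(13.0 * t, 36.0) / 36.0 * 3.3
        speed = feat.wheel_speed(v, rate)
        assert np.allclose(speed[2:-2], 13.0, rtol=0.01)

    def test_empty_trace_error(self):
        with pytest.raises(ValueError):
            feat.wheel_speed(np.array([]), 100.0)


class TestEyeApertures:
    def test_regular_octagon_aperture(self):
        ang = np.deg2rad(np.arange(0, 360, 45))
        pts = 1.3 * np.stack([np.cos(ang), np.sin(ang)], axis=-1)
        assert np.allclose(feat.octagon_aperture(pts[None]), 2.6)

    def test_hand_computed_distance(self):
        pts = np.array([[[0.3, 1.0], [0.0, -0.5], [0.2, 0.2], [0.1, 0.0],
                         [0.15, 0.3], [0.05, -0.2], [0.0, 0.1],
                         [0.25, 0.4]]])
        assert np.allclose(feat.octagon_aperture(pts),
                           np.sqrt(2.34), atol=1e-6)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            feat.octagon_aperture(np.zeros((1, 1, 2)))

    def test_all_punished_frames_imputed(self):
        trials = pd.DataFrame({
            "t_start": [0.0, 13.0], "duration": [13.0, 5.0],
            "punished": [True, False],
            "t_onset": [1.0, 14.0]})
        # frames only inside the first trial's punishment extension
        frame_times = np.array([6.0, 7.0, 13.5, 14.0])
        pts = np.tile(np.array([[0, 1.0], [0, -1.0], [1, 0], [-1, 0],
                                [0.7, 0.7], [-0.7, 0.7], [0.7, -0.7],
                                [-0.7, -0.7]]), (4, 1, 1))
        vals, imputed = feat.eye_apertures(pts, frame_times, trials)
        assert imputed[0] and not imputed[1]
        assert np.allclose(vals, 2.0)   # imputed from the session median


class TestLickMetrics:
    def test_no_licks(self):
        trials = pd.DataFrame({"t_start": [0.0], "t_onset": [1.0]})
        whole, pre = feat.lick_metrics(np.array([]), trials)
        assert whole[0] == 0 and pre[0] == 0

    def test_ten_licks_two_hz(self):
        trials = pd.DataFrame({"t_start": [0.0], "t_onset": [1.0]})
        whole, pre = feat.lick_metrics(np.linspace(1.1, 4.9, 10), trials)
        assert whole[0] == 2.0

    def test_half_open_boundary_assignment(self):
        trials = pd.DataFrame({"t_start": [0.0, 5.0],
                               "t_onset": [1.0, 6.0]})
        licks = np.array([0.0, 4.999, 5.0, 9.999, 10.0])
        whole, _ = feat.lick_metrics(licks, trials)
        # [0,5) gets 2 licks, [5,10) gets 2, the lick at 10.0 neither
        assert np.allclose(whole * cfg.TRIAL_CORE_S, [2, 2])

    def test_prestim_window(self):
        trials = pd.DataFrame({"t_start": [0.0], "t_onset": [1.0]})
        _, pre = feat.lick_metrics(np.array([0.0, 0.5, 0.999, 1.0]), trials)
        assert pre[0] == 3


class TestSpectra:
    @pytest.mark.parametrize("alpha,tol", [(0.0, 0.15), (1.0, 0.3),
                                           (2.0, 0.3)])
    def test_pss_recovers_exponent(self, alpha, tol):
        slopes = [feat.prestim_pss(
            powerlaw_noise(1250, alpha, np.random.default_rng(s),
                           n_channels=2), 1250.0)
            for s in range(50)]
        assert abs(np.mean(slopes) + alpha) < tol

    def test_pss_scale_invariance(self):
        x = powerlaw_noise(1250, 1.0, np.random.default_rng(0), n_channels=3)
        assert np.isclose(feat.prestim_pss(x, 1250.0),
                          feat.prestim_pss(7.3 * x, 1250.0))

    def test_pss_short_epoch_error(self):
        with pytest.raises(ValueError):
            feat.prestim_pss(np.zeros((2, 600)), 1250.0)

    def test_mua_power_zero_signal(self):
        assert feat.mua_band_power(np.zeros((3, 20000)), 20000.0) == 0.0

    def test_mua_power_quadratic_in_amplitude(self):
        x = np.random.default_rng(1).standard_normal((2, 20000))
        p1 = feat.mua_band_power(x, 20000.0)
        p2 = feat.mua_band_power(2 * x, 20000.0)
        assert np.isclose(p2, 4 * p1, rtol=1e-9)

    def test_mua_power_band_limited_noise(self):
        from scipy import signal as sps
        rng = np.random.default_rng(2)
        broad = rng.standard_normal((1, 20000))
        sos = sps.butter(8, 400.0, "lowpass", fs=20000.0, output="sos")
        low = sps.sosfiltfilt(sos, broad)
        assert feat.mua_band_power(low, 20000.0) <= \
            0.01 * feat.mua_band_power(broad, 20000.0)

    def test_mua_power_nyquist_error(self):
        with pytest.raises(ValueError):
            feat.mua_band_power(np.zeros((1, 5000)), 5000.0)

    def test_evoked_single_sample_identity(self):
        lfp = np.full((1, 25), 4.2)
        raw = np.random.default_rng(0).standard_normal((1, 4000))
        e_lfp, _ = feat.evoked_responses(lfp, raw, 125.0, 20000.0, 0.0)
        assert np.isclose(e_lfp, 4.2)

    def test_evoked_monotone_in_dipole_amplitude(self, small_mouse):
        """Doubling the generator's evoked amplitude doubles the feature."""
        from conftest import small_mouse_config
        amps = []
        for gain in (1.0, 2.0):
            c = small_mouse_config(n_sessions=1, trials_per_session=25)
            coup = c.feature_coupling["evoked_lfp"]
            coup.means = {k: gain * v for k, v in coup.means.items()}
            tl = ms.gen_state_timeline(c)
            tr = ms.gen_trials(tl, c)
            stm = ms.gen_session_streams(tl, tr, c, rng=3)
            table = feat.build_feature_table(tr, stm)
            amps.append(table["evoked_lfp"].mean())
        assert abs(amps[1]) > abs(amps[0])


class TestSessionSummaries:
    def test_all_correct_session_peak_one(self):
        table = pd.DataFrame({
            "mouse": "m", "day": 1, "correctness": 1,
            "wheel_speed": 0.0, "prestim_pss": -1.0,
            "prestim_mua_power": 1.0, "whole_trial_lick_rate": 2.0,
            "pupil_diameter": 1.0, "eyelid_aperture": 2.0,
        }, index=range(100))
        with pytest.warns(UserWarning, match="single session"):
            summ, _ = feat.session_summaries(table)
        assert summ.peak_correctness.iloc[0] == 1.0

    def test_learning_trend_detected(self):
        rng = np.random.default_rng(0)
        rows = []
        for day in range(1, 9):
            p = 0.5 + 0.05 * day
            rows.append(pd.DataFrame({
                "mouse": "m", "day": day,
                "correctness": rng.random(200) < p,
                "wheel_speed": rng.normal(size=200),
                "prestim_pss": -1.0, "prestim_mua_power": 1.0,
                "whole_trial_lick_rate": 2.0, "pupil_diameter": 1.0,
                "eyelid_aperture": 2.0}))
        _, trends = feat.session_summaries(pd.concat(rows))
        row = trends.set_index("metric").loc["peak_correctness"]
        assert row.r > 0 and row.p < 0.05

    def test_stream_features_recover_state_means(self, small_mouse,
                                                 small_features):
        """End-to-end parameter recovery: extraction from synthesized
        streams recovers the configured per-state feature means."""
        coup = small_mouse.config.feature_coupling
        for var in ("prestim_lick_rate", "wheel_speed", "pupil_diameter",
                    "eyelid_aperture"):
            for state, g in small_features.groupby("latent_state"):
                drift = coup[var].drift.get(state, 0.0)
                expect = coup[var].means[state] + drift * (
                    g["day"].to_numpy() - 1)
                se = max(g[var].std(ddof=1) / np.sqrt(len(g)), 1e-3)
                assert abs(g[var].mean() - expect.mean()) < 2.5 * se + 0.3, \
                    (var, state)
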