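import numpy as np
import pytest

from rowkinetics import preprocess as pp
from rowkinetics.datamodel import SensorStream


class TestIntegrateAndHighpass:
    def test_constant_acceleration_drift_removed(self):
        fs = 100.0
        accel = np.full(int(60 * fs), 0.2)
        v = pp.integrate_and_highpass(accel, fs)
        assert abs(v.mean()) < 0.01

    def test_sinusoid_amplitude_matches_analytic_integral(self):
        fs, f, a = 100.0, 0.5, 1.0
        t = np.arange(int(60 * fs)) / fs
        v = pp.integrate_and_highpass(a * np.sin(2 * np.pi * f * t), fs)
        mid = v[int(10 * fs) : int(50 * fs)]  # away from filter edges
        expected = a / (2 * np.pi * f)
        assert np.max(np.abs(mid)) == pytest.approx(expected, rel=0.05)

    def test_zero_input_gives_zero_output(self):
        v = pp.integrate_and_highpass(np.zeros(4000), 100.0)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_too_short_stream_rejected(self):
        with pytest.raises(pp.PreprocessError, match="too_short"):
            pp.integrate_and_highpass(np.zeros(100), 100.0)


class TestSynchronize:
    def _signal(self, fs=100.0, n_s=60.0, seed=0):
        # quasi-periodic, like a boat-velocity trace, with incommensurate
        # harmonics and noise breaking exact periodicity
        rng = np.random.default_rng(seed)
        t = np.arange(int(n_s * fs)) / fs
        return (np.sin(2 * np.pi * 0.55 * t) + 0.3 * np.sin(2 * np.pi * 1.27 * t + 1.0)
                + 0.1 * rng.normal(size=len(t)))

    def test_identical_signals_lag_zero(self):
        x = self._signal()
        res = pp.synchronize(x, x, 100.0)
        assert res.lag_s == 0.0
        assert res.correlation == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("delay_s", [-2.0, -0.8, 0.0, 0.8, 2.0])
    def test_planted_delay_recovered_within_one_sample(self, delay_s):
        fs = 100.0
        full = self._signal(fs, n_s=70.0)
        n = int(60 * fs)
        pad = int(5 * fs)
        k = int(round(delay_s * fs))
        x = full[pad : pad + n]
        delayed = full[pad - k : pad - k + n]  # delayed[i] = x[i - k]
        res = pp.synchronize(x, delayed, fs, max_lag_s=3.0)
        # aligning requires advancing the delayed copy: lag = -delay
        assert abs(res.lag_s - (-delay_s)) <= 1.0 / fs + 1e-12

    def test_independent_noise_fails(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=1000), rng.normal(size=1000)
        with pytest.raises(pp.SyncError, match="sync_failed"):
            pp.synchronize(a, b, 100.0)


class TestResample:
    def test_same_rate_is_identity(self, rng):
        s = SensorStream(50.0, 0.0, ["x"], rng.normal(size=(200, 1)))
        out = pp.resample(s, 50.0)
        np.testing.assert_allclose(out.values, s.values, atol=1e-12)

    def test_linear_ramp_is_exact(self):
        t = np.arange(100) / 50.0
        s = SensorStream(50.0, 0.0, ["x"], (2.0 * t)[:, None])
        out = pp.resample(s, 100.0)
        np.testing.assert_allclose(out.values[:, 0], 2.0 * out.time_s, atol=1e-12)

    def test_sinusoid_interpolation_error_below_1pct(self):
        fs = 50.0
        t = np.arange(int(10 * fs)) / fs
        s = SensorStream(fs, 0.0, ["x"], np.sin(2 * np.pi * 2.0 * t)[:, None])
        out = pp.resample(s, 100.0)
        expected = np.sin(2 * np.pi * 2.0 * out.time_s)
        assert np.max(np.abs(out.values[:, 0] - expected)) < 0.01


class TestDifferentiate:
    def test_linear_ramp_exact_including_edges(self):
        x = 2.0 * np.arange(100) / 50.0
        np.testing.assert_allclose(pp.differentiate(x, 50.0), 2.0, atol=1e-9)

    def test_constant_gives_zero(self):
        np.testing.assert_allclose(pp.differentiate(np.full(50, 3.3), 50.0), 0.0)

    def test_sinusoid_derivative_amplitude(self):
        fs, f = 100.0, 2.0  # f = fs/50
        t = np.arange(int(5 * fs)) / fs
        d = pp.differentiate(np.sin(2 * np.pi * f * t), fs)
        assert np.max(np.abs(d[10:-10])) == pytest.approx(2 * np.pi * f, rel=0.01)


class TestSegmentCycles:
    def test_sinusoid_ten_periods_gives_nine_cycles(self):
        fs, period = 50.0, 2.5
        t = np.arange(int(10 * period * fs)) / fs
        x = np.sin(2 * np.pi * t / period)
        cycles = pp.segment_cycles(x, fs)
        assert len(cycles) == 9
        for c in cycles:
            # catch sits at the analytic minimum between the two finishes
            assert x[c.catch_idx] == pytest.approx(-1.0, abs=1e-3)
            assert c.stroke_rate_spm == pytest.approx(60.0 / period, rel=0.02)

    def test_constant_reference_gives_no_cycles(self):
        assert pp.segment_cycles(np.ones(1000), 50.0) == []

    def test_overlong_cycle_discarded(self):
        fs, period = 50.0, 2.5
        # 4 normal periods, one stretched beyond max_cycle_s, 4 normal periods
        t1 = np.arange(int(4 * period * fs)) / fs
        t2 = np.arange(int(8.0 * fs)) / fs  # stretched period of 8 s
        phase = np.concatenate([
            2 * np.pi * t1 / period,
            2 * np.pi * (4 + t2 / 8.0),
            2 * np.pi * (5 + t1 / period),
        ])
        x = np.sin(phase)
        permissive = pp.segment_cycles(x, fs, max_cycle_s=10.0)
        strict = pp.segment_cycles(x, fs, max_cycle_s=6.0)
        # exactly one finish-to-finish cycle spans the stretched period
        assert len(strict) == len(permissive) - 1
        assert all(c.n_samples / fs <= 6.0 for c in strict)

    def test_segmentation_idempotent_on_simulated_session(self, ergo_session_clean):
        x = ergo_session_clean.streams["ergo"].channel("X_handle")
        fs = ergo_session_clean.streams["ergo"].sample_rate_hz
        first = pp.segment_cycles(x, fs)
        again = pp.segment_cycles(x, fs)
        assert [(c.start_idx, c.catch_idx, c.end_idx) for c in first] == \
               [(c.start_idx, c.catch_idx, c.end_idx) for c in again]
        assert len(first) >= len(ergo_session_clean.cycles) - 1


def drive_phase_oracle(force, on=196.2, off=98.1):
    """Linear-scan reference for the threshold drive-phase detector."""
    start = None
    for i, f in enumerate(force):
        if f > on:
            start = i
            break
    if start is None:
        return None
    for j in range(start, len(force)):
        if force[j] < off:
            return start, j
    return start, len(force)


class TestDetectDrivePhase:
    def test_triangular_profile_matches_oracle(self):
        force = np.concatenate([np.linspace(0, 300, 50), np.linspace(300, 0, 50)])
        got = pp.detect_drive_phase(force)
        assert got == drive_phase_oracle(force)

    def test_random_profiles_match_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(30, 200)
            force = np.maximum(
                rng.normal(150, 120, n) + 200 * np.sin(np.linspace(0, np.pi, n)), 0
            )
            oracle = drive_phase_oracle(force)
            if oracle is None:
                with pytest.raises(pp.DriveDetectionError):
                    pp.detect_drive_phase(force)
            else:
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    assert pp.detect_drive_phase(force) == oracle

    def test_force_below_onset_raises(self):
        with pytest.raises(pp.DriveDetectionError, match="no_drive_detected"):
            pp.detect_drive_phase(np.full(100, 50.0))

    def test_force_always_above_offset_runs_to_cycle_end(self):
        with pytest.warns(UserWarning):
            assert pp.detect_drive_phase(np.full(100, 250.0)) == (0, 100)

    def test_drive_window_inside_catch_to_finish(self, ergo_session_clean):
        sess = ergo_session_clean
        force = sess.clean_streams["ergo"].channel("F_handle")
        cycles = pp.attach_drive_phase([c for c in sess.cycles], force)
        assert cycles
        for c in cycles:
            assert c.catch_idx <= c.drive_start_idx < c.drive_end_idx <= c.end_idx


class TestDropArtifactCycles:
    def test_nan_cycle_dropped(self, ergo_session_clean):
        sess = ergo_session_clean
        x = sess.streams["ergo"].channel("X_handle").copy()
        bad = sess.cycles[2]
        x[bad.catch_idx] = np.nan
        kept = pp.drop_artifact_cycles(sess.cycles, {"X_handle": x})
        assert bad not in kept
        assert len(kept) == len(sess.cycles) - 1
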