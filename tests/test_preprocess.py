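import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from respco2.io import PhysioRecording, WaveformSeries
from respco2.preprocess import (PreprocessConfig, correct_delay,
                                estimate_breathing_rate, lowpass,
                                preprocess_pipeline, qa_evaluate, znormalize)
from respco2.synthetic import make_qa_failure_fixture


def _sin(freq, fs=50.0, dur=120.0, amp=1.0):
    t = np.arange(0, dur, 1.0 / fs)
    return WaveformSeries(amp * np.sin(2 * np.pi * freq * t), fs)


class TestLowpass:
    def test_dc_passthrough(self):
        s = WaveformSeries(np.full(1000, 2.5), 50.0)
        out = lowpass(s, 1.0)
        np.testing.assert_allclose(out.values, 2.5, atol=1e-9)

    def test_stopband_attenuation(self):
        out = lowpass(_sin(5.0), 1.0)
        # 5 Hz is > 2 octaves above the 1 Hz cutoff: residual < 1 %
        assert np.abs(out.values[100:-100]).max() < 0.01

    def test_passband_amplitude_and_zero_phase(self):
        s = _sin(0.3)
        out = lowpass(s, 1.0)
        mid = slice(500, -500)
        assert np.abs(out.values[mid] - s.values[mid]).max() < 0.02

    def test_one_octave_attenuation_exceeds_40db(self):
        out = lowpass(_sin(2.0), 1.0)
        assert np.abs(out.values[200:-200]).max() < 10 ** (-40 / 20)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass(_sin(0.3, fs=10.0), 5.0)


class TestCorrectDelay:
    def test_zero_lag_anticorrelated_pair(self):
        t = np.arange(0, 100, 0.1)
        resp = WaveformSeries(np.sin(2 * np.pi * 0.3 * t), 10.0)
        co2 = WaveformSeries(-np.sin(2 * np.pi * 0.3 * t), 10.0)
        rec = PhysioRecording("s", "r", resp, co2)
        _, delay = correct_delay(rec, 5.0)
        assert delay == 0.0

    def test_no_negative_correlation_returns_zero_lag(self):
        ramp = np.linspace(0, 1, 1000)
        rec = PhysioRecording("s", "r", WaveformSeries(ramp, 10.0),
                              WaveformSeries(ramp.copy(), 10.0))
        out, delay = correct_delay(rec, 5.0)
        assert delay == 0.0
        assert out.meta["delay_correlation"] >= 0

    def test_mismatched_rates_rejected(self):
        rec = PhysioRecording("s", "r", _sin(0.3, fs=50.0), _sin(0.3, fs=25.0))
        with pytest.raises(ValueError, match="sampling rate"):
            correct_delay(rec, 5.0)

    def test_trimming_keeps_common_support(self, default_sim):
        rec = default_sim.recording.copy()
        rec.resp = lowpass(rec.resp, 1.0)
        rec.co2 = lowpass(rec.co2, 1.0)
        out, delay = correct_delay(rec, 20.0)
        assert out.resp.n == out.co2.n
        assert out.resp.n == rec.resp.n - int(round(delay * rec.resp.fs))


class TestZnormalize:
    def test_moments(self):
        out = znormalize(_sin(0.3))
        assert abs(out.values.mean()) < 1e-10
        assert abs(out.values.std() - 1.0) < 1e-10

    def test_population_sd_convention(self):
        out = znormalize(WaveformSeries(np.array([0.0, 2.0]), 1.0))
        np.testing.assert_allclose(out.values, [-1.0, 1.0])

    def test_constant_is_hard_error(self):
        with pytest.raises(ValueError, match="constant"):
            znormalize(WaveformSeries(np.full(100, 3.0), 10.0))

    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
    def test_affine_invariance_and_idempotence(self, a, b):
        rng = np.random.default_rng(0)
        x = WaveformSeries(rng.standard_normal(500), 10.0)
        z = znormalize(x)
        scaled = WaveformSeries(a * x.values + b, 10.0)
        np.testing.assert_allclose(znormalize(scaled).values, z.values, atol=1e-8)
        np.testing.assert_allclose(znormalize(z).values, z.values, atol=1e-10)


class TestQA:
    def test_short_recording_rejected_by_duration_gate(self):
        out = make_qa_failure_fixture("too_short", seed=0)
        _, report = preprocess_pipeline(out.recording)
        assert report.duration_s < 180
        assert not report.duration_ok
        assert not report.accepted

    def test_weak_coupling_rejected_by_r_gate_only(self):
        out = make_qa_failure_fixture("weak_coupling", seed=0)
        _, report = preprocess_pipeline(out.recording)
        assert report.r_after_delay > -0.4
        assert not report.r_ok
        assert report.duration_ok and not report.lf_flag
        assert not report.accepted

    def test_acceptance_requires_duration_and_r(self, default_sim):
        _, report = preprocess_pipeline(default_sim.recording)
        assert report.accepted == (report.duration_ok and report.r_ok)
        assert report.accepted

    def test_r_ok_implies_threshold(self, default_sim):
        _, report = preprocess_pipeline(default_sim.recording)
        assert report.r_ok
        assert report.r_after_delay <= -0.4

    def test_report_is_pure_function_of_recording(self, default_sim):
        rec = default_sim.recording
        from respco2.preprocess import lowpass as lp
        work = rec.copy()
        work.resp = lp(work.resp, 1.0)
        work.co2 = lp(work.co2, 1.0)
        work, _ = correct_delay(work, 20.0)
        r1 = qa_evaluate(work)
        r2 = qa_evaluate(work)
        assert r1 == r2


class TestPipeline:
    def test_default_recording_fully_processed(self, default_sim):
        proc, report = preprocess_pipeline(default_sim.recording)
        assert report.accepted
        assert proc.resp.fs == pytest.approx(10.0)
        assert proc.co2.fs == pytest.approx(10.0)
        assert proc.resp.n == proc.co2.n
        for chan in (proc.resp, proc.co2):
            assert abs(chan.values.mean()) < 1e-9
            assert abs(chan.values.std() - 1.0) < 1e-9
        assert proc.normalized

    def test_rejected_recording_keeps_native_rate(self):
        out = make_qa_failure_fixture("too_short", seed=1)
        proc, report = preprocess_pipeline(out.recording)
        assert not report.accepted
        assert proc.resp.fs == out.recording.resp.fs
        assert not proc.normalized

    def test_adaptive_cutoff_mode(self, default_sim):
        cfg = PreprocessConfig(cutoff_hz="adaptive")
        proc, report = preprocess_pipeline(default_sim.recording, cfg)
        assert report.accepted

    def test_breathing_rate_estimate(self, default_sim):
        rate = estimate_breathing_rate(default_sim.recording.resp)
        assert rate == pytest.approx(default_sim.params.breath_rate_hz, abs=0.05)
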