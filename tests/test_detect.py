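"""Detector behaviour: exact recovery without noise, ground-truth matching
with noise, and the invariances the measurements must satisfy."""

import numpy as np
import pytest

import quantalysis as q
from quantalysis.detect import MiniEventDetector, match_events
from quantalysis.simulate import kernel_half_rise_delay


def _mini_trace(times, amp, cfg, seed=0):
    return q.synthesize_trace([(t, amp) for t in times], cfg, seed=seed)


class TestMiniDetection:
    def test_flat_trace_no_events(self, quiet_config):
        tr = q.synthesize_trace([], quiet_config, seed=0)
        assert len(q.detect_minis(tr, threshold=0.5)) == 0

    def test_exact_recovery_noiseless(self, quiet_config):
        times = [0.2 + 0.3 * i for i in range(5)]
        tr = _mini_trace(times, 1.0, quiet_config)
        events = q.detect_minis(tr, threshold=0.5)
        assert len(events) == 5
        assert np.allclose(events["amplitude"], 1.0, rtol=0.01)

    def test_empty_trace_error(self):
        tr = q.TraceRecording(samples=np.empty(0), sampling_rate=1e4)
        with pytest.raises(ValueError):
            q.detect_minis(tr, threshold=0.5)

    def test_nonpositive_threshold_error(self, quiet_config):
        tr = q.synthesize_trace([], quiet_config, seed=0)
        with pytest.raises(ValueError):
            q.detect_minis(tr, threshold=0.0)

    def test_snr5_precision_recall(self):
        cfg = q.RecordingConfig(sampling_rate=10_000, duration=100.0,
                                noise_sd=0.2, mini_rate=2.0)
        model = q.ReleaseModel(q_mean=1.0, q_cv=0.0)
        tr = q.synthesize_trace([], cfg, seed=0, release_model=model)
        events = q.detect_minis(tr, threshold=0.5)
        truth = (np.array(tr.metadata["truth"]["mini_times"])
                 + kernel_half_rise_delay(cfg.kernel_rise, cfg.kernel_decay))
        precision, recall, _ = match_events(events["time"], truth, tol=0.002)
        assert precision >= 0.95
        assert recall >= 0.95

    def test_translation_invariance(self, quiet_config):
        times = [0.3, 0.8, 1.3]
        tr1 = _mini_trace(times, 1.0, quiet_config)
        tr2 = _mini_trace([t + 0.25 for t in times], 1.0, quiet_config)
        e1 = q.detect_minis(tr1, threshold=0.5)
        e2 = q.detect_minis(tr2, threshold=0.5)
        assert np.allclose(e2["time"] - e1["time"], 0.25, atol=2e-4)
        assert np.allclose(e1["amplitude"], e2["amplitude"], rtol=1e-6)

    def test_amplitude_linearity(self, quiet_config):
        tr = _mini_trace([0.5, 1.2], 1.0, quiet_config)
        scaled = q.TraceRecording(samples=3.0 * tr.samples,
                                  sampling_rate=tr.sampling_rate)
        a1 = q.detect_minis(tr, threshold=0.5)["amplitude"].to_numpy()
        a2 = q.detect_minis(scaled, threshold=1.5)["amplitude"].to_numpy()
        assert np.allclose(a2, 3.0 * a1, rtol=1e-9)

    def test_performance_degrades_with_noise(self):
        model = q.ReleaseModel(q_mean=1.0, q_cv=0.0)
        f1 = []
        for noise in (0.1, 0.45):
            cfg = q.RecordingConfig(sampling_rate=10_000, duration=40.0,
                                    noise_sd=noise, mini_rate=2.0)
            tr = q.synthesize_trace([], cfg, seed=5, release_model=model)
            ev = q.detect_minis(tr, threshold=0.5)
            truth = (np.array(tr.metadata["truth"]["mini_times"])
                     + kernel_half_rise_delay(cfg.kernel_rise,
                                              cfg.kernel_decay))
            p, r, _ = match_events(ev["time"], truth, tol=0.002)
            f1.append(2 * p * r / (p + r))
        assert f1[1] <= f1[0]

    def test_refractory_merges_doublets(self, quiet_config):
        tr = _mini_trace([0.5, 0.502], 1.0, quiet_config)
        events = q.detect_minis(tr, threshold=0.5, refractory=0.005)
        assert len(events) == 1

    def test_tevc_sign_convention(self):
        cfg = q.RecordingConfig(duration=2.0, noise_sd=0.0, mini_rate=0.0,
                                mode="tevc")
        tr = q.synthesize_trace([(0.5, 0.8)], cfg, seed=0)
        events = q.detect_minis(tr, threshold=0.4)
        assert len(events) == 1
        assert events["amplitude"].iloc[0] == pytest.approx(0.8, rel=0.01)


class TestEvokedMeasurement:
    def test_single_stimulus_exact(self):
        cfg = q.RecordingConfig(duration=0.3, noise_sd=0.0, mini_rate=0.0,
                                mode="tevc")
        tr = q.synthesize_trace([(0.05, 40.0)], cfg, seed=0,
                                stim_times=[0.05])
        out = q.measure_evoked(tr, window=0.05)
        assert out["amplitude"].iloc[0] == pytest.approx(40.0, rel=0.01)

    def test_no_deflection_gives_zero(self, quiet_config):
        tr = q.synthesize_trace([], quiet_config, seed=0)
        tr.stim_times = np.array([0.5])
        out = q.measure_evoked(tr, window=0.05)
        assert out["amplitude"].iloc[0] == 0.0

    def test_no_stimuli_error(self, quiet_config):
        tr = q.synthesize_trace([], quiet_config, seed=0)
        with pytest.raises(ValueError):
            q.measure_evoked(tr)

    def test_train_amplitudes_match_generator(self):
        # non-overlapping kernels: fast decay versus 60 Hz spacing
        model = q.ReleaseModel(q_mean=0.6, q_cv=0.3)
        pool = q.PoolModel()
        train = q.simulate_train(model, pool, 3.0, n_stim=60, freq=60.0,
                                 seed=8)
        cfg = q.RecordingConfig(duration=1.4, noise_sd=0.0, mini_rate=0.0,
                                kernel_rise=0.0005, kernel_decay=0.003,
                                mode="tevc")
        stim_times = 0.1 + train.stimulus_times
        tr = q.synthesize_trace(list(zip(stim_times, train.amplitudes)),
                                cfg, seed=0, stim_times=stim_times)
        out = q.measure_evoked(tr, window=1 / 60.0, baseline_window=0.002,
                               smoothing=0.0)
        assert np.allclose(out["amplitude"], train.amplitudes,
                           rtol=0.02, atol=0.02)

    def test_measurement_linearity(self):
        cfg = q.RecordingConfig(duration=0.3, noise_sd=0.0, mini_rate=0.0)
        tr = q.synthesize_trace([(0.05, 7.0)], cfg, seed=0, stim_times=[0.05])
        scaled = q.TraceRecording(samples=2.5 * tr.samples,
                                  sampling_rate=tr.sampling_rate,
                                  stim_times=tr.stim_times)
        a = q.measure_evoked(tr)["amplitude"].iloc[0]
        b = q.measure_evoked(scaled)["amplitude"].iloc[0]
        assert b == pytest.approx(2.5 * a, rel=1e-9)


class TestEstimatorInterface:
    def test_get_set_params_roundtrip(self):
        det = MiniEventDetector(threshold=0.7)
        params = det.get_params()
        assert params["threshold"] == 0.7
        det.set_params(refractory=0.01)
        assert det.refractory == 0.01
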